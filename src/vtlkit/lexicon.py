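"""Key-phrase lexicons used to classify LLM response texts.

These lists are fixed vocabularies: 27 phrases whose presence marks an
interpretation answer as negative (the model declined or disclaimed
knowledge), 11 phrases whose presence marks a pairwise-reasoning answer as
positive, and the single standalone negative keyword "no" that overrides a
reasoning phrase.  Do not edit them; the classifiers' semantics depend on
these exact strings.
"""

from __future__ import annotations

#: Presence of any of these marks an interpretation response NEGATIVE.
INTERPRETATION_NEGATIVE_PHRASES: tuple[str, ...] = (
    "am not able",
    "am unable",
    "cannot access",
    "cannot conclude",
    "cannot confirm",
    "cannot find",
    "cannot provide",
    "cannot retrieve",
    "cannot say",
    "cannot state",
    "cannot tell",
    "couldn't find",
    "do not currently have",
    "do not have",
    "do not know",
    "don't have",
    "don't know",
    "has not been determined",
    "no documented evidence",
    "no evidence",
    "no known connection",
    "no known direct association",
    "no published research",
    "no scientific evidence to",
    "not able to provide",
    "not clear",
    "not found to be directly involved",
)

#: Presence of any of these (absent the negative keyword) marks a
#: pairwise-reasoning response POSITIVE.
REASONING_POSITIVE_PHRASES: tuple[str, ...] = (
    "can reason",
    "could reason",
    "can be reasoned",
    "could be reasoned",
    "reasonable",
    "can be hypothesized",
    "can hypothesize",
    "can be inferred",
    "can infer",
    "can reasonably assume",
    "plausible to hypothesize",
)

#: Standalone word that negates a reasoning response (whole-word match).
REASONING_NEGATIVE_KEYWORD = "no"

assert len(INTERPRETATION_NEGATIVE_PHRASES) == 27
assert len(REASONING_POSITIVE_PHRASES) == 11
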
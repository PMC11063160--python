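"""Prompt construction, key-phrase response classification, and
confusion-matrix evaluation with negative-set resampling.

The workflow this supports: a protein-function question is posed per fly
protein isoform and per behavior (standard two-round prompting), free-text
answers are classified positive/negative by fixed key-phrase lexicons, and
the resulting gene-level calls are scored against curated benchmark gene
lists with sensitivity, specificity, accuracy, precision and the Matthews
correlation coefficient.  Because the unreported-gene universe is much
larger than any benchmark, specificity is estimated by repeatedly sampling
a 1:1 negative set and averaging over rounds.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from math import sqrt
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .lexicon import (
    INTERPRETATION_NEGATIVE_PHRASES,
    REASONING_NEGATIVE_KEYWORD,
    REASONING_POSITIVE_PHRASES,
)

BEHAVIORS = ("sleep", "locomotor activity", "social activity")

_WS = re.compile(r"\s+")
_NO_WORD = re.compile(rf"\b{REASONING_NEGATIVE_KEYWORD}\b")


def normalize_text(text: str) -> str:
    """Case-fold, collapse whitespace, unify curly apostrophes/quotes.

    Idempotent: ``normalize_text(normalize_text(t)) == normalize_text(t)``.
    """
    text = text.replace("’", "'").replace("‘", "'")
    text = text.replace("“", '"').replace("”", '"')
    return _WS.sub(" ", text).strip().casefold()


def classify_interpretation_response(text: str) -> bool:
    """True (positive) iff the text contains none of the 27 negative phrases."""
    norm = normalize_text(text)
    return not any(p in norm for p in INTERPRETATION_NEGATIVE_PHRASES)


def classify_reasoning_response(text: str) -> bool:
    """True (positive) iff a reasoning phrase is present and the standalone
    word "no" is absent (whole-word, case-insensitive)."""
    norm = normalize_text(text)
    if _NO_WORD.search(norm):
        return False
    return any(p in norm for p in REASONING_POSITIVE_PHRASES)


# ---------------------------------------------------------------------------
# Prompt construction
# ---------------------------------------------------------------------------

def _symbol(protein_full_name: str) -> str:
    """Bare symbol from a full name like 'Dop1R1 (Dopamine 1-like receptor 1, isoform E)'."""
    return protein_full_name.split(" (", 1)[0]


def build_standard_prompt(protein_full_name: str, behavior: str) -> tuple[str, str]:
    """Two-round standard prompt for one protein isoform and one behavior.

    Round 1 asks for the protein's function and whether it regulates the
    behavior; round 2 primes the affirmative answer and requests the chain
    of thought plus a validating experimental plan.
    """
    if not protein_full_name:
        raise ValueError("protein name must be non-empty")
    if behavior not in BEHAVIORS:
        raise ValueError(f"behavior must be one of {BEHAVIORS}")
    symbol = _symbol(protein_full_name)
    round1 = (
        f"Can you tell me the function of the fruit fly protein "
        f"“{protein_full_name}”? Is the protein “{symbol}” "
        f"involved in regulating {behavior}?"
    )
    round2 = (
        f"We have known that fruit fly protein {protein_full_name} is involved "
        f"in regulating the {behavior} of fruit flies. Why do you consider this "
        f"protein {protein_full_name} involved in regulating {behavior}? Please "
        f"tell me the chain of thought one by one.\n\n"
        f"According to the chain of thought you mentioned, which experiments "
        f"must be performed to validate this function in {behavior} regulation? "
        f"Please list the experimental plan one by one."
    )
    return round1, round2


def build_cot_prompt(gene_a_description: str, gene_b_description: str) -> str:
    """Pairwise gene-relationship query requesting the chain of thought."""
    if not gene_a_description or not gene_b_description:
        raise ValueError("both gene descriptions must be non-empty")
    return (
        f"{gene_a_description} {gene_b_description} What are the potential "
        f"relationships between these two genes? Please tell me the chain of "
        f"thought of your reasoning one by one."
    )


def iter_genome_prompts(
    isoform_full_names: Iterable[str],
    behaviors: Sequence[str] = BEHAVIORS,
) -> Iterator[tuple[str, str, str]]:
    """Yield ``(isoform, behavior, round-1 prompt)`` for every combination.

    Each protein isoform is queried once per behavior, so the number of
    prompt-generation pairs is ``n_isoforms * len(behaviors)``.
    """
    for name in isoform_full_names:
        for behavior in behaviors:
            yield name, behavior, build_standard_prompt(name, behavior)[0]


# ---------------------------------------------------------------------------
# Confusion counts and metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Sn, Sp, Ac, Pr in [0, 1] and MCC in [-1, 1].

    Sn = TP/(TP+FN), Sp = TN/(TN+FP), Ac = (TP+TN)/total, Pr = TP/(TP+FP),
    MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN)).
    Any zero denominator yields 0 by convention.
    """

    sn: float
    sp: float
    ac: float
    pr: float
    mcc: float


def _ratio(num: float, den: float) -> float:
    return num / den if den else 0.0


def metrics_from_counts(counts: ConfusionCounts) -> MetricSet:
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    mcc = (tp * tn - fn * fp) / sqrt(denom) if denom else 0.0
    return MetricSet(
        sn=_ratio(tp, tp + fn),
        sp=_ratio(tn, tn + fp),
        ac=_ratio(tp + tn, counts.total),
        pr=_ratio(tp, tp + fp),
        mcc=mcc,
    )


def evaluate_predictions(
    predictions: Mapping[str, bool],
    positive_benchmark: Iterable[str],
    negative_set: Iterable[str],
) -> tuple[ConfusionCounts, MetricSet]:
    """Score gene-level positive/negative calls against benchmark gene sets.

    ``predictions`` maps gene symbol -> called positive; genes absent from
    the mapping count as called negative.  The positive benchmark and the
    negative set must be disjoint.
    """
    pos = set(positive_benchmark)
    neg = set(negative_set)
    if pos & neg:
        raise ValueError(f"benchmark sets overlap: {sorted(pos & neg)[:5]} ...")
    called = lambda g: bool(predictions.get(g, False))
    tp = sum(1 for g in pos if called(g))
    fn = len(pos) - tp
    fp = sum(1 for g in neg if called(g))
    tn = len(neg) - fp
    counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
    return counts, metrics_from_counts(counts)


def resampled_specificity(
    predictions: Mapping[str, bool],
    unreported_gene_pool: Sequence[str],
    n_positives: int,
    rounds: int = 20,
    seed: int = 0,
    positive_benchmark: Iterable[str] | None = None,
) -> dict:
    """Average specificity over repeated 1:1 negative resampling.

    Each round draws ``n_positives`` genes without replacement from the
    unreported pool as the negative set.  When ``positive_benchmark`` is
    given, full per-round metric sets (against the fixed positives) are
    returned as well; with a 1:1 design, per-round Ac = (Sn + Sp) / 2.
    """
    pool = list(unreported_gene_pool)
    if len(pool) < n_positives:
        raise ValueError("unreported gene pool smaller than the positive set")
    rng = np.random.default_rng(seed)
    pos = sorted(set(positive_benchmark)) if positive_benchmark is not None else []
    per_round_sp: list[float] = []
    per_round_metrics: list[MetricSet] = []
    per_round_counts: list[ConfusionCounts] = []
    for _ in range(rounds):
        negatives = [pool[i] for i in rng.choice(len(pool), n_positives, replace=False)]
        fp = sum(1 for g in negatives if predictions.get(g, False))
        tn = n_positives - fp
        per_round_sp.append(_ratio(tn, tn + fp))
        if pos:
            counts, mset = evaluate_predictions(predictions, pos, negatives)
            per_round_metrics.append(mset)
            per_round_counts.append(counts)
    result = {
        "sp_per_round": per_round_sp,
        "sp_mean": float(np.mean(per_round_sp)),
        "rounds": rounds,
    }
    if per_round_counts:
        result["counts_per_round"] = per_round_counts
    if per_round_metrics:
        for name in ("sn", "ac", "pr", "mcc"):
            result[f"{name}_mean"] = float(
                np.mean([getattr(m, name) for m in per_round_metrics])
            )
        result["metrics_per_round"] = per_round_metrics
    return result


def positive_response_rate(responses: pd.DataFrame) -> dict[str, float]:
    """Fraction of interpretation-positive responses per behavior.

    Expects columns ``behavior`` and ``response_text``.
    """
    if responses.empty:
        raise ValueError("response table is empty")
    out: dict[str, float] = {}
    for behavior, group in responses.groupby("behavior", sort=True):
        calls = group["response_text"].map(classify_interpretation_response)
        out[str(behavior)] = float(calls.mean())
    return out


def read_benchmark(path: str | Path, symbol_column: str = "gene_symbol") -> set[str]:
    """Load a curated benchmark gene list (TSV with symbol + accession columns)."""
    df = pd.read_csv(path, sep="\t")
    if symbol_column not in df.columns:
        raise ValueError(f"benchmark file lacks a '{symbol_column}' column")
    return set(df[symbol_column].astype(str))


def gene_level_calls(
    isoform_calls: Mapping[str, bool],
    isoform_to_gene: Mapping[str, str],
) -> dict[str, bool]:
    """Reduce isoform-level calls to gene level: positive if any isoform is."""
    out: dict[str, bool] = {}
    for isoform, call in isoform_calls.items():
        gene = isoform_to_gene.get(isoform, isoform)
        out[gene] = out.get(gene, False) or bool(call)
    return out
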
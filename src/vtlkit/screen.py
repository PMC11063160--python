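"""Hit calling for genome-wide behavioural screens.

Each per-line phenotype table (one row per RNAi/mutant line) is scored
against its own population statistics, candidate included:

* sleep: hit when daily sleep is strictly below mean - 2 * SD (sample SD);
* locomotor: hit when daily distance is at least 1.5x the population mean;
* social: hit when interaction duration is at most 0.5x the population mean.

``overlap_sets`` reports the seven Venn regions of the three hit sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("line_id", "gene_symbol", "value")


@dataclass(frozen=True)
class ScreenTable:
    """A validated per-line phenotype table with population statistics."""

    table: pd.DataFrame
    population_mean: float
    population_sd: float

    @classmethod
    def from_frame(cls, table: pd.DataFrame, min_lines: int = 1) -> "ScreenTable":
        missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"screen table lacks columns: {missing}")
        if len(table) < min_lines:
            raise ValueError(f"screen table needs at least {min_lines} lines")
        values = table["value"].to_numpy(dtype=float)
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        return cls(table=table, population_mean=float(values.mean()), population_sd=sd)


def _as_screen_table(table, min_lines: int = 1) -> ScreenTable:
    if isinstance(table, ScreenTable):
        return table
    return ScreenTable.from_frame(table, min_lines=min_lines)


def call_sleep_hits(table: pd.DataFrame | ScreenTable) -> set[str]:
    """Lines with phenotype strictly below mean - 2 SD (short sleepers)."""
    st = _as_screen_table(table, min_lines=3)
    if st.population_sd == 0:
        return set()
    cutoff = st.population_mean - 2.0 * st.population_sd
    mask = st.table["value"].to_numpy(dtype=float) < cutoff
    return set(st.table.loc[mask, "line_id"])


def call_locomotor_hits(table: pd.DataFrame | ScreenTable) -> set[str]:
    """Lines with daily distance >= 1.5x the population mean."""
    st = _as_screen_table(table)
    mask = st.table["value"].to_numpy(dtype=float) >= 1.5 * st.population_mean
    return set(st.table.loc[mask, "line_id"])


def call_social_hits(table: pd.DataFrame | ScreenTable) -> set[str]:
    """Lines with social interaction duration <= 0.5x the population mean."""
    st = _as_screen_table(table)
    mask = st.table["value"].to_numpy(dtype=float) <= 0.5 * st.population_mean
    return set(st.table.loc[mask, "line_id"])


def hits_to_genes(table: pd.DataFrame, hit_lines: set[str]) -> set[str]:
    """Map hit line ids to gene symbols (a gene is a hit if any line is)."""
    sel = table["line_id"].isin(hit_lines)
    return set(table.loc[sel, "gene_symbol"])


def overlap_sets(
    sleep_hits: set[str],
    locomotor_hits: set[str],
    social_hits: set[str],
) -> dict[str, int]:
    """Cardinalities of the 7 Venn regions of the three hit sets.

    Keys name the exclusive regions (``sleep_only``, ``sleep_locomotor``,
    ..., ``all_three``); symbols are compared case-sensitively.
    """
    s, l, c = set(sleep_hits), set(locomotor_hits), set(social_hits)
    return {
        "sleep_only": len(s - l - c),
        "locomotor_only": len(l - s - c),
        "social_only": len(c - s - l),
        "sleep_locomotor": len((s & l) - c),
        "sleep_social": len((s & c) - l),
        "locomotor_social": len((l & c) - s),
        "all_three": len(s & l & c),
    }


def read_screen_table(path) -> pd.DataFrame:
    """Read a per-line phenotype table from TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"screen table lacks columns: {missing}")
    return df
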
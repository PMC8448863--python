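"""Downstream pulsed-SILAC protein synthesis analysis.

Starting from a proteinGroups-style table of per-protein heavy/medium (H/M)
isotope ratios at two pulse timepoints (+24 h and 48 h of coculture), the
pipeline: (1) drops decoy, contaminant and modified-peptide-only records and
records without a single valid ratio; (2) converts to log2 and centres each
timepoint; (3) classifies proteins as co-downregulated / co-upregulated /
discordant across the two timepoints; (4) reports pathways over-represented
among co-downregulated proteins by two-sided Fisher exact test at 5% BH FDR,
retaining only pathways with enrichment factor above 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrich import EnrichmentRow, SetDB, bh_adjust, fisher_exact_2x2

__all__ = [
    "RATIO_COLUMNS",
    "FLAG_COLUMNS",
    "FilterCounts",
    "SilacResult",
    "read_ratio_table",
    "write_ratio_table",
    "filter_records",
    "log2_normalize",
    "cross_coregulation",
    "pathway_report",
]

RATIO_COLUMNS = ["ratio_hm_t24", "ratio_hm_t48"]
FLAG_COLUMNS = ["reverse", "contaminant", "only_modified"]
_REQUIRED = ["protein_id", *RATIO_COLUMNS, *FLAG_COLUMNS]


@dataclass
class FilterCounts:
    """Records removed per rule, applied in this order."""

    decoy: int = 0
    contaminant: int = 0
    modified_only: int = 0
    no_valid_value: int = 0

    def total(self) -> int:
        return self.decoy + self.contaminant + self.modified_only + self.no_valid_value

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.decoy, self.contaminant, self.modified_only, self.no_valid_value)


@dataclass
class SilacResult:
    """Normalised log2(H/M) per protein and timepoint plus co-regulation sets."""

    table: pd.DataFrame  # protein_id, log2_t24, log2_t48 (normalised)
    method: str = "median-center"
    co_down: frozenset = field(default_factory=frozenset)
    co_up: frozenset = field(default_factory=frozenset)
    discordant: frozenset = field(default_factory=frozenset)


def _validate_columns(records: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED if c not in records.columns]
    if missing:
        raise ValueError(f"ratio table is missing columns: {missing}")


def read_ratio_table(path: str | Path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a minimal proteinGroups-dialect TSV.

    ``column_map`` renames source columns (e.g. a real MaxQuant export) onto
    the canonical names ``protein_id, ratio_hm_t24, ratio_hm_t48, reverse,
    contaminant, only_modified``. Flags accept MaxQuant's "+" convention,
    booleans, or 0/1.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if column_map:
        df = df.rename(columns=column_map)
    _validate_columns(df)
    for col in FLAG_COLUMNS:
        df[col] = df[col].map(
            lambda v: str(v).strip() in {"+", "True", "true", "1", "1.0"}
        )
    for col in RATIO_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def write_ratio_table(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index=False)


def filter_records(records: pd.DataFrame) -> tuple[pd.DataFrame, FilterCounts]:
    """Apply the record-level exclusion rules in order.

    Order: decoy (reverse) hits, then potential contaminants, then proteins
    identified only by modified peptides, then records without at least one
    valid H/M ratio. Returns the surviving records and per-rule counts;
    counts are additive (input = output + sum of removals).
    """
    _validate_columns(records)
    df = records.copy()
    counts = FilterCounts()

    rule = df["reverse"].astype(bool)
    counts.decoy = int(rule.sum())
    df = df[~rule]

    rule = df["contaminant"].astype(bool)
    counts.contaminant = int(rule.sum())
    df = df[~rule]

    rule = df["only_modified"].astype(bool)
    counts.modified_only = int(rule.sum())
    df = df[~rule]

    valid = df[RATIO_COLUMNS].notna().any(axis=1)
    counts.no_valid_value = int((~valid).sum())
    df = df[valid]

    return df.reset_index(drop=True), counts


def log2_normalize(records: pd.DataFrame, method: str = "median-center") -> SilacResult:
    """Convert H/M ratios to log2 and centre each timepoint.

    ``method`` is ``"median-center"`` (default; per-timepoint median of the
    normalised values becomes 0) or ``"mean-center"``. Present ratios must be
    positive; the offending protein is named otherwise.
    """
    _validate_columns(records)
    if method not in ("median-center", "mean-center"):
        raise ValueError("method must be 'median-center' or 'mean-center'")
    out = records[["protein_id"]].copy()
    for src, dst in zip(RATIO_COLUMNS, ("log2_t24", "log2_t48")):
        vals = records[src].to_numpy(dtype=float)
        bad = np.isfinite(vals) & (vals <= 0)
        if bad.any():
            who = records.loc[bad, "protein_id"].iloc[0]
            raise ValueError(f"non-positive H/M ratio for protein {who!r} in {src}")
        with np.errstate(invalid="ignore"):
            logs = np.log2(vals)
        present = np.isfinite(logs)
        if present.any():
            centre = np.nanmedian(logs[present]) if method == "median-center" else np.nanmean(logs[present])
        else:
            centre = 0.0
        out[dst] = logs - centre
    return SilacResult(table=out, method=method)


def cross_coregulation(result: SilacResult, margin: float = 0.0) -> SilacResult:
    """Classify proteins by the sign of the normalised log2 ratio at both timepoints.

    co_down: below ``-margin`` at both timepoints; co_up symmetric; discordant:
    opposite signs (both beyond the margin). Proteins missing a timepoint or
    inside the +/-margin band at either timepoint stay unclassified.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    t = result.table
    a = t["log2_t24"].to_numpy(dtype=float)
    b = t["log2_t48"].to_numpy(dtype=float)
    ids = t["protein_id"].to_numpy()
    both = np.isfinite(a) & np.isfinite(b)
    neg_a, neg_b = a < -margin, b < -margin
    pos_a, pos_b = a > margin, b > margin
    co_down = frozenset(ids[both & neg_a & neg_b])
    co_up = frozenset(ids[both & pos_a & pos_b])
    discordant = frozenset(ids[both & ((neg_a & pos_b) | (pos_a & neg_b))])
    return SilacResult(
        table=t,
        method=result.method,
        co_down=co_down,
        co_up=co_up,
        discordant=discordant,
    )


def pathway_report(
    co_down,
    universe,
    db: SetDB,
    fdr: float = 0.05,
    min_enrichment: float = 2.0,
) -> tuple[pd.DataFrame, list[EnrichmentRow]]:
    """Pathways over-represented among co-downregulated proteins.

    Each pathway is tested with a two-sided Fisher exact test on the 2x2 table
    (in co_down vs not) x (in pathway vs not) over the filtered-protein
    universe, BH-corrected across pathways. The report keeps rows with
    q <= ``fdr`` and enrichment factor > ``min_enrichment``, sorted by
    enrichment factor descending. Returns (report table, all tested rows).
    """
    hits = set(co_down)
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    stray = hits - uni
    if stray:
        raise ValueError(f"co_down not contained in universe: {sorted(stray)[:10]}")
    N, n = len(uni), len(hits)
    rows: list[EnrichmentRow] = []
    for pathway, members in db.sets.items():
        K = len(members & uni)
        if K == 0:
            continue
        k = len(members & hits)
        a, b = k, n - k
        c, d = K - k, N - K - (n - k)
        pval = fisher_exact_2x2(a, b, c, d)
        ef = (k / n) / (K / N) if n > 0 else 0.0
        rows.append(EnrichmentRow(set_name=pathway, k=k, K=K, n=n, N=N, enrichment_factor=ef, p=pval, direction="down"))
    if rows:
        qs = bh_adjust([r.p for r in rows])
        for r, q in zip(rows, qs):
            r.q = float(max(q, r.p))
    kept = [r for r in rows if r.q <= fdr and r.enrichment_factor > min_enrichment]
    kept.sort(key=lambda r: -r.enrichment_factor)
    report = pd.DataFrame(
        {
            "pathway": [r.set_name for r in kept],
            "k": [r.k for r in kept],
            "K": [r.K for r in kept],
            "n": [r.n for r in kept],
            "N": [r.N for r in kept],
            "enrichment_factor": [r.enrichment_factor for r in kept],
            "p": [r.p for r in kept],
            "q": [r.q for r in kept],
        }
    )
    return report, rows
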
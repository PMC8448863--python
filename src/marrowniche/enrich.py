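"""Set-enrichment statistics.

Shared machinery for kinase-substrate enrichment analysis (KSEA) over
phosphoproteomic differential results, ontology over-representation of hit
lists, and the exact tests (hypergeometric upper tail, two-sided Fisher) plus
Benjamini-Hochberg correction that every enrichment report in this package is
built on.

The exact tests are computed with log-factorial arithmetic rather than
delegated, so they can be validated against exhaustive enumeration of the
hypergeometric support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SetDB",
    "EnrichmentRow",
    "ZClassification",
    "bh_adjust",
    "hypergeom_pvalue",
    "hypergeom_randomized_pvalue",
    "fisher_exact_2x2",
    "enrichment_factor",
    "ksea",
    "ksea_zscore",
    "classify_z",
    "ontology_enrichment",
    "enrichment_table",
]


# ---------------------------------------------------------------------------
# set database


@dataclass
class SetDB:
    """Named sets of identifiers (kinase substrates, GO terms, pathways).

    Membership is stored as ``name -> frozenset`` with duplicates removed.
    """

    sets: dict[str, frozenset] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, frozenset] = {}
        for name, members in self.sets.items():
            fs = frozenset(members)
            if not fs:
                raise ValueError(f"set {name!r} is empty")
            clean[name] = fs
        self.sets = clean

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def all_members(self) -> frozenset:
        out: set = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)

    @classmethod
    def from_gmt(cls, path: str | Path) -> "SetDB":
        """Read a GMT file: one set per line, ``name<TAB>description<TAB>members...``."""
        sets: dict[str, frozenset] = {}
        desc: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (need >=3 fields): {line[:80]!r}")
            name, description, members = parts[0], parts[1], parts[2:]
            members = [m for m in members if m]
            if name in sets:
                raise ValueError(f"duplicate set name in GMT: {name!r}")
            sets[name] = frozenset(members)
            desc[name] = description
        return cls(sets=sets, descriptions=desc)

    def to_gmt(self, path: str | Path) -> None:
        lines = []
        for name, members in self.sets.items():
            description = self.descriptions.get(name, "na")
            lines.append("\t".join([name, description, *sorted(members)]))
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# result containers


@dataclass
class EnrichmentRow:
    """One enrichment test: k of n hits fall in a set of K among N total."""

    set_name: str
    k: int
    K: int
    n: int
    N: int
    enrichment_factor: float
    p: float
    q: float = float("nan")
    z: float = float("nan")
    direction: str = "both"

    def __post_init__(self) -> None:
        if not 0 <= self.k <= min(self.K, self.n):
            raise ValueError(f"invalid counts for {self.set_name}: k={self.k}, K={self.K}, n={self.n}")
        if self.K > self.N or self.n > self.N:
            raise ValueError(f"K and n must not exceed N for {self.set_name}")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p out of [0,1] for {self.set_name}")


@dataclass
class ZClassification:
    z: float
    threshold: float = 1.5
    label: str = field(init=False)

    def __post_init__(self) -> None:
        if self.z >= self.threshold:
            self.label = "overrepresented"
        elif self.z <= -self.threshold:
            self.label = "underrepresented"
        else:
            self.label = "neutral"


# ---------------------------------------------------------------------------
# exact-test primitives


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def _log_binom(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def _hypergeom_logpmf(k: int, N: int, K: int, n: int) -> float:
    return _log_binom(K, k) + _log_binom(N - K, n - k) - _log_binom(N, n)


def _check_hypergeom_bounds(k: int, K: int, n: int, N: int) -> None:
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v:
            raise ValueError(f"{name} must be an integer, got {v!r}")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"require 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")


def hypergeom_pvalue(k: int, K: int, n: int, N: int, mid_p: bool = False) -> float:
    """Inclusive upper tail P[X >= k] for X ~ Hypergeometric(N, K, n).

    Drawing n items from a universe of N containing K marked items, the
    probability of observing k or more marked draws. Exact log-factorial sum.

    With ``mid_p=True`` returns P[X > k] + P[X = k]/2 instead — the mid-p
    transform, whose null distribution has mean 1/2 and is far closer to
    uniform than the conservative inclusive tail of a discrete statistic.
    Used for calibration diagnostics, not for inference.
    """
    _check_hypergeom_bounds(k, K, n, N)
    k, K, n, N = int(k), int(K), int(n), int(N)
    support_lo = max(0, n - (N - K))
    if k <= support_lo and not mid_p:
        return 1.0  # tail covers the whole support
    lo = max(k, support_lo)
    hi = min(K, n)
    if lo > hi:
        return 1.0 if k <= support_lo else 0.0
    logs = [_hypergeom_logpmf(j, N, K, n) for j in range(lo, hi + 1)]
    mx = max(logs)
    weights = [1.0] * len(logs)
    if mid_p and lo == k:
        weights[0] = 0.5
    p = math.exp(mx) * sum(wt * math.exp(v - mx) for wt, v in zip(weights, logs))
    return float(min(1.0, p))


def hypergeom_randomized_pvalue(k: int, K: int, n: int, N: int, u: float) -> float:
    """Randomized (PIT) upper-tail p: P[X > k] + u * P[X = k], u in [0, 1].

    For a correctly computed null CDF this is exactly Uniform(0, 1) under the
    null when u is an independent Uniform(0, 1) draw; used only as a
    calibration diagnostic for the discrete hypergeometric test.
    """
    if not 0.0 <= u <= 1.0:
        raise ValueError("u must lie in [0, 1]")
    p_incl = hypergeom_pvalue(k, K, n, N)
    lo = max(0, n - (N - K))
    pmf = math.exp(_hypergeom_logpmf(k, N, K, n)) if lo <= k <= min(K, n) else 0.0
    p_excl = max(0.0, p_incl - pmf)
    return float(min(1.0, p_excl + u * pmf))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums the probabilities of all tables with the observed margins whose
    point probability does not exceed that of the observed table (within a
    relative tolerance of 1e-7, to make the rule robust to rounding).
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if int(v) != v or v < 0:
            raise ValueError(f"table entries must be non-negative integers; {name}={v!r}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    N = a + b + c + d
    if N == 0:
        return 1.0
    K = a + b          # row-1 margin
    n = a + c          # col-1 margin
    lo = max(0, n - (N - K))
    hi = min(K, n)
    log_obs = _hypergeom_logpmf(a, N, K, n)
    cutoff = log_obs + math.log1p(1e-7)
    logs = [_hypergeom_logpmf(j, N, K, n) for j in range(lo, hi + 1)]
    keep = [v for v in logs if v <= cutoff]
    mx = max(keep)
    p = math.exp(mx) * sum(math.exp(v - mx) for v in keep)
    return float(min(1.0, p))


def enrichment_factor(k: int, K: int, n: int, N: int) -> float:
    """Fold over-representation (k/n) / (K/N) of a set among hits."""
    if n <= 0 or K <= 0 or N <= 0:
        raise ValueError(f"require n > 0, K > 0, N > 0; got n={n}, K={K}, N={N}")
    return (k / n) / (K / N)


# ---------------------------------------------------------------------------
# KSEA


def ksea_zscore(fold_changes_all: Sequence[float], member_fold_changes: Sequence[float]) -> float:
    """Substrate-set z score from fold changes.

    z = (mean(member FC) - mean(all FC)) * sqrt(m) / sd(all FC), where m is
    the member count and sd is the population standard deviation over the
    whole universe of fold changes.
    """
    all_fc = np.asarray(fold_changes_all, dtype=float)
    mem = np.asarray(member_fold_changes, dtype=float)
    if mem.size == 0:
        raise ValueError("member fold-change set is empty")
    sd = float(np.std(all_fc))
    if sd == 0.0:
        raise ValueError("global fold-change standard deviation is zero")
    return float((mem.mean() - all_fc.mean()) * math.sqrt(mem.size) / sd)


def classify_z(z: float, threshold: float = 1.5) -> ZClassification:
    """Classify a set z score: over- if z >= +threshold, under- if z <= -threshold."""
    if not math.isfinite(z):
        raise ValueError("z must be finite")
    return ZClassification(z=float(z), threshold=float(threshold))


def ksea(
    diff,
    db: SetDB,
    sig_p: float = 0.05,
    universe: str = "annotated",
    z_threshold: float = 1.5,
    p_mode: str = "inclusive",
    rng: np.random.Generator | None = None,
) -> list[EnrichmentRow]:
    """Kinase-substrate enrichment analysis over differential phosphorylation results.

    Parameters
    ----------
    diff
        Sequence of objects (or DataFrame rows) with attributes/columns
        ``peptide_id``, ``log2fc`` and ``p`` — the output of
        :func:`marrowniche.phospho.differential`.
    db
        Kinase -> substrate-peptide sets.
    sig_p
        Raw (non-adjusted) p-value cut below which a peptide counts as
        regulated; sign of log2fc gives the direction.
    universe
        ``"annotated"`` (default): universe N = peptides mapping to at least
        one substrate set. ``"all"``: every peptide with a finite p.
    p_mode
        ``"inclusive"`` (default) reports the inclusive upper tail P[X >= k];
        ``"mid"`` the mid-p transform; ``"randomized"`` the randomized PIT
        (requires ``rng``), which is exactly uniform under the null and is
        meant only for calibration diagnostics.
    """
    if len(db) == 0:
        raise ValueError("set database is empty")
    if p_mode not in ("inclusive", "mid", "randomized"):
        raise ValueError("p_mode must be 'inclusive', 'mid' or 'randomized'")
    if p_mode == "randomized" and rng is None:
        raise ValueError("p_mode='randomized' requires an rng")
    if isinstance(diff, pd.DataFrame):
        table = diff.loc[:, ["peptide_id", "log2fc", "p"]].copy()
    else:
        table = pd.DataFrame(
            [(r.peptide_id, r.log2fc, r.p) for r in diff],
            columns=["peptide_id", "log2fc", "p"],
        )
    table = table[np.isfinite(table["p"]) & np.isfinite(table["log2fc"])]
    annotated = db.all_members()
    if universe == "annotated":
        table = table[table["peptide_id"].isin(annotated)]
    elif universe != "all":
        raise ValueError("universe must be 'annotated' or 'all'")
    if len(table) == 0:
        raise ValueError("empty universe: no annotated peptides with finite statistics")

    ids = table["peptide_id"].to_numpy()
    fc = table["log2fc"].to_numpy()
    p = table["p"].to_numpy()
    universe_ids = set(ids)
    N = len(table)
    sig = {
        "up": set(ids[(p < sig_p) & (fc > 0)]),
        "down": set(ids[(p < sig_p) & (fc < 0)]),
    }
    fc_by_id = dict(zip(ids, fc))

    rows: list[EnrichmentRow] = []
    for kinase, members in db.sets.items():
        in_universe = members & universe_ids
        K = len(in_universe)
        member_fc = [fc_by_id[m] for m in in_universe]
        if K > 0 and np.std(fc) > 0:
            z = ksea_zscore(fc, member_fc)
        else:
            z = float("nan")
        for direction in ("up", "down"):
            n = len(sig[direction])
            k = len(in_universe & sig[direction])
            if K == 0 or n == 0:
                pval = 1.0 if p_mode != "randomized" else float(rng.random())
                ef = 0.0
            else:
                if p_mode == "inclusive":
                    pval = hypergeom_pvalue(k, K, n, N)
                elif p_mode == "mid":
                    pval = hypergeom_pvalue(k, K, n, N, mid_p=True)
                else:
                    pval = hypergeom_randomized_pvalue(k, K, n, N, float(rng.random()))
                ef = enrichment_factor(k, K, n, N) if k > 0 else 0.0
            rows.append(
                EnrichmentRow(
                    set_name=kinase, k=k, K=K, n=n, N=N,
                    enrichment_factor=ef, p=pval, z=z, direction=direction,
                )
            )
    qs = bh_adjust([r.p for r in rows])
    for r, q in zip(rows, qs):
        r.q = float(max(q, r.p))
    return rows


# ---------------------------------------------------------------------------
# ontology / pathway over-representation


def ontology_enrichment(
    hits: Iterable[str],
    universe: Iterable[str],
    db: SetDB,
) -> list[EnrichmentRow]:
    """Hypergeometric over-representation of each set among ``hits``.

    ``hits`` must be a subset of ``universe``; terms are restricted to their
    members inside the universe, tested with the inclusive upper tail, and
    BH-corrected across all tested terms.
    """
    hit_set = set(hits)
    uni_set = set(universe)
    stray = hit_set - uni_set
    if stray:
        shown = ", ".join(sorted(stray)[:10])
        raise ValueError(f"hits not contained in universe: {shown}")
    if not uni_set:
        raise ValueError("empty universe")
    N = len(uni_set)
    n = len(hit_set)
    rows: list[EnrichmentRow] = []
    for term, members in db.sets.items():
        K = len(members & uni_set)
        if K == 0:
            continue
        k = len(members & hit_set)
        pval = hypergeom_pvalue(k, K, n, N) if n > 0 else 1.0
        ef = enrichment_factor(k, K, n, N) if n > 0 else 0.0
        rows.append(EnrichmentRow(set_name=term, k=k, K=K, n=n, N=N, enrichment_factor=ef, p=pval))
    if rows:
        qs = bh_adjust([r.p for r in rows])
        for r, q in zip(rows, qs):
            r.q = float(max(q, r.p))
    return rows


def enrichment_table(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    """Flatten enrichment rows to the standard TSV column layout."""
    return pd.DataFrame(
        {
            "set": [r.set_name for r in rows],
            "direction": [r.direction for r in rows],
            "k": [r.k for r in rows],
            "K": [r.K for r in rows],
            "n": [r.n for r in rows],
            "N": [r.N for r in rows],
            "enrichment_factor": [r.enrichment_factor for r in rows],
            "p": [r.p for r in rows],
            "q": [r.q for r in rows],
            "z": [r.z for r in rows],
            "class": [
                classify_z(r.z).label if math.isfinite(r.z) else "na" for r in rows
            ],
        }
    )
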
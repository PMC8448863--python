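"""Synthetic pulsed-SILAC protein tables with planted co-regulation and pathways.

Emulates a proteinGroups-style export from a two-timepoint pulse experiment:
per-protein H/M ratios at +24 h and 48 h, decoy / contaminant /
modified-peptide-only flags at chosen rates, missing values, a planted
fraction of co-downregulated proteins (negative true log2 ratio at both
timepoints), and a pathway database in which planted pathways concentrate
their members among the co-downregulated set while background pathways draw
members uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..enrich import SetDB

__all__ = ["SilacSimParams", "gen_silac_table"]


@dataclass
class SilacSimParams:
    n_proteins: int = 520
    fraction_decoy: float = 0.03
    fraction_contaminant: float = 0.02
    fraction_modified_only: float = 0.02
    fraction_missing: float = 0.02      # records with no valid ratio at all
    fraction_one_timepoint: float = 0.03  # clean records missing one timepoint
    fraction_co_down: float = 0.3
    effect_log2: float = -1.0           # planted true log2 ratio of co-down proteins
    noise_sd_log2: float = 0.1
    planted_pathways: list[tuple[str, int, str]] = field(
        default_factory=lambda: [("PLANTED_DOWN_1", 20, "down")]
    )
    pathway_hit_fraction: float = 0.9   # of a planted down-pathway's members in co-down truth
    n_background_pathways: int = 20
    background_pathway_size: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fraction_decoy",
            "fraction_contaminant",
            "fraction_modified_only",
            "fraction_missing",
            "fraction_one_timepoint",
            "fraction_co_down",
            "pathway_hit_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        flagged = self.fraction_decoy + self.fraction_contaminant + self.fraction_modified_only
        if flagged + self.fraction_missing > 1.0:
            raise ValueError("flag + missing fractions exceed 1")


def gen_silac_table(params: SilacSimParams) -> tuple[pd.DataFrame, SetDB, pd.DataFrame]:
    """Generate (ratio table, pathway SetDB, truth table); deterministic per seed.

    The truth table records every protein's flags, planted true log2 ratios,
    and co-down membership. Flag groups (decoy, contaminant, modified-only,
    all-missing) are disjoint, so the sequential filter removes each record
    exactly once.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_proteins
    ids = np.array([f"P{i:05d}" for i in range(n)])

    n_decoy = int(round(params.fraction_decoy * n))
    n_cont = int(round(params.fraction_contaminant * n))
    n_mod = int(round(params.fraction_modified_only * n))
    n_miss = int(round(params.fraction_missing * n))
    order = rng.permutation(n)
    decoy_idx = order[:n_decoy]
    cont_idx = order[n_decoy : n_decoy + n_cont]
    mod_idx = order[n_decoy + n_cont : n_decoy + n_cont + n_mod]
    miss_idx = order[n_decoy + n_cont + n_mod : n_decoy + n_cont + n_mod + n_miss]
    clean_idx = order[n_decoy + n_cont + n_mod + n_miss :]

    reverse = np.zeros(n, dtype=bool)
    contaminant = np.zeros(n, dtype=bool)
    only_modified = np.zeros(n, dtype=bool)
    reverse[decoy_idx] = True
    contaminant[cont_idx] = True
    only_modified[mod_idx] = True

    # clean records missing exactly one timepoint stay in the table but are
    # unclassifiable for cross-timepoint co-regulation
    n_one = int(round(params.fraction_one_timepoint * len(clean_idx)))
    one_tp_idx = clean_idx[:n_one]
    both_tp_idx = clean_idx[n_one:]

    n_down = int(round(params.fraction_co_down * len(both_tp_idx)))
    down_idx = rng.permutation(both_tp_idx)[:n_down]
    co_down_true = np.zeros(n, dtype=bool)
    co_down_true[down_idx] = True

    true_log2 = np.zeros((n, 2))
    true_log2[co_down_true] = params.effect_log2
    obs_log2 = true_log2 + rng.normal(0.0, params.noise_sd_log2, size=(n, 2)) \
        if params.noise_sd_log2 > 0 else true_log2.copy()

    ratios = 2.0**obs_log2
    ratio_t24 = ratios[:, 0].copy()
    ratio_t48 = ratios[:, 1].copy()
    ratio_t24[miss_idx] = np.nan
    ratio_t48[miss_idx] = np.nan
    for i, idx in enumerate(one_tp_idx):
        if i % 2 == 0:
            ratio_t24[idx] = np.nan
        else:
            ratio_t48[idx] = np.nan

    table = pd.DataFrame(
        {
            "protein_id": ids,
            "ratio_hm_t24": ratio_t24,
            "ratio_hm_t48": ratio_t48,
            "reverse": reverse,
            "contaminant": contaminant,
            "only_modified": only_modified,
        }
    )

    # pathway database over the surviving universe
    survivors = np.ones(n, dtype=bool)
    survivors[decoy_idx] = survivors[cont_idx] = False
    survivors[mod_idx] = False
    survivors[miss_idx] = False
    surv_ids = ids[survivors]
    down_ids = ids[co_down_true & survivors]
    other_ids = np.array(sorted(set(surv_ids) - set(down_ids)))

    sets: dict[str, frozenset] = {}
    for name, size, direction in params.planted_pathways:
        n_hit = int(round(params.pathway_hit_fraction * size))
        n_hit = min(n_hit, len(down_ids))
        n_bg = min(size - n_hit, len(other_ids))
        if direction == "down":
            members = list(rng.choice(down_ids, size=n_hit, replace=False)) + list(
                rng.choice(other_ids, size=n_bg, replace=False)
            )
        else:  # a non-regulated planted pathway: members drawn uniformly
            members = list(rng.choice(surv_ids, size=min(size, len(surv_ids)), replace=False))
        if members:  # a fully flagged universe can leave a pathway empty
            sets[name] = frozenset(members)
    for b in range(params.n_background_pathways):
        size = min(params.background_pathway_size, len(surv_ids))
        if size == 0:
            break
        members = rng.choice(surv_ids, size=size, replace=False)
        sets[f"BG_PATHWAY_{b + 1}"] = frozenset(members)
    db = SetDB(sets=sets)

    truth = pd.DataFrame(
        {
            "protein_id": ids,
            "reverse": reverse,
            "contaminant": contaminant,
            "only_modified": only_modified,
            "all_missing": np.isin(np.arange(n), miss_idx),
            "true_log2_t24": true_log2[:, 0],
            "true_log2_t48": true_log2[:, 1],
            "co_down_true": co_down_true,
        }
    )
    return table, db, truth
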
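"""Ground-truth recovery benchmarks.

Each function generates synthetic inputs with the synth module, runs the
corresponding analysis stage, and measures recovery against the planted
truth. These are the package's standing accuracy experiments: the test suite
asserts thresholds on their outputs and ``scripts/acceptance.py`` reports the
raw numbers.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage.draw import disk as draw_disk

from .enrich import ksea
from .histo import (
    SegmentationParams,
    crack_perimeter,
    segment_image,
    shape_filter,
)
from .phospho import XICParams, differential, differential_table, normalize_heights, quantify
from .silac import cross_coregulation, filter_records, log2_normalize, pathway_report
from .synth import (
    MarrowImageParams,
    PhosphoSimParams,
    SilacSimParams,
    gen_marrow_image,
    gen_phospho_matrix,
    gen_phospho_raw,
    gen_silac_table,
    kinase_setdb,
)

__all__ = [
    "histomorphometry_recovery",
    "cluster_separation_benchmark",
    "shape_oracle",
    "xic_recovery",
    "phospho_null_calibration",
    "ksea_recovery",
    "ksea_null_uniformity",
    "silac_coregulation_recovery",
    "silac_pathway_detection",
]


def _match_objects(truth_df: pd.DataFrame, objects) -> tuple[np.ndarray, np.ndarray]:
    """Greedy nearest-centroid matching of recovered objects to planted truth.

    Returns (matched mask over truth rows, relative area errors of matches).
    """
    tc = truth_df[["centroid_row", "centroid_col"]].to_numpy()
    ta = truth_df["area_um2"].to_numpy()
    if not objects:
        return np.zeros(len(truth_df), bool), np.array([])
    rc = np.array([o.centroid for o in objects])
    ra = np.array([o.area_um2 for o in objects])
    d = np.sqrt(((tc[:, None, :] - rc[None, :, :]) ** 2).sum(-1))
    matched = np.zeros(len(truth_df), bool)
    rel_err = []
    used = np.zeros(len(objects), bool)
    for i in np.argsort(d.min(axis=1)):
        j = int(np.argmin(np.where(used, np.inf, d[i])))
        if not used[j] and d[i, j] < 15.0:
            used[j] = True
            matched[i] = True
            rel_err.append(abs(ra[j] - ta[i]) / ta[i])
    return matched, np.asarray(rel_err)


def histomorphometry_recovery(n_images: int = 20, seed: int = 0) -> dict[str, float]:
    """Count and size recovery on the standard 50-adipocyte benchmark.

    Measures, over seeded non-overlapping-object images: the fraction of
    images whose recovered count is within +/-5% of truth, and the pooled
    per-object relative area error (mean absolute, percent) of
    centroid-matched objects.
    """
    within = 0
    errors: list[np.ndarray] = []
    for i in range(n_images):
        img, roi, truth = gen_marrow_image(MarrowImageParams(seed=seed + i))
        objects, _, summary = segment_image(img, roi)
        if abs(summary.n_adipocytes - truth.true_count) <= 0.05 * truth.true_count:
            within += 1
        _, rel = _match_objects(truth.objects, objects)
        errors.append(rel)
    pooled = np.concatenate(errors) if errors else np.array([np.nan])
    return {
        "count_within_5pct_frac": within / n_images,
        "area_mae_pct": float(100.0 * pooled.mean()),
        "n_images": n_images,
    }


def cluster_separation_benchmark(n_images: int = 20, seed: int = 100) -> dict[str, float]:
    """Fraction of planted touching pairs resolved into two objects.

    A pair counts as resolved when both members have a recovered object whose
    centroid lies within 5 um of the planted centroid.
    """
    total = resolved = 0
    for i in range(n_images):
        img, roi, truth = gen_marrow_image(
            MarrowImageParams(cluster_fraction=0.3, seed=seed + i)
        )
        objects, _, _ = segment_image(img, roi)
        rc = np.array([o.centroid for o in objects]) if objects else np.zeros((0, 2))
        um = img.pixel_size_um
        by_label = truth.objects.set_index("label")
        for l1, l2 in truth.pairs:
            total += 1
            hits = 0
            for lab in (l1, l2):
                c = by_label.loc[lab, ["centroid_row", "centroid_col"]].to_numpy(float)
                if len(rc) and np.sqrt(((rc - c) ** 2).sum(1)).min() * um <= 5.0:
                    hits += 1
            resolved += hits == 2
    return {
        "pair_resolution_frac": resolved / total if total else float("nan"),
        "n_pairs": total,
    }


def shape_oracle() -> dict[str, float]:
    """Form-factor accuracy on rasterised disks and the elongated-rectangle control."""
    ffs = []
    for r in range(10, 61, 5):
        mask = np.zeros((2 * r + 9, 2 * r + 9), bool)
        rr, cc = draw_disk((r + 4, r + 4), r + 0.5)
        mask[rr, cc] = True
        objs = shape_filter(
            mask.astype(np.int32), 1.0,
            SegmentationParams(min_area_um2=10.0, max_area_um2=1e8, min_form_factor=0.0),
        )
        ffs.append(objs[0].form_factor)
    rect = np.zeros((20, 120), bool)
    rect[8:12, 10:110] = True
    perim = crack_perimeter(rect)
    rect_ff = 4 * math.pi * 400 / perim**2
    closed_form = 4 * math.pi * 400 / 208**2
    return {
        "disk_ff_min": float(min(ffs)),
        "disk_ff_max": float(max(ffs)),
        "rect_ff": float(rect_ff),
        "rect_ff_abs_err": float(abs(rect_ff - closed_form)),
    }


def xic_recovery(n_peptides: int = 500, seed: int = 0) -> dict[str, float]:
    """Planted-amplitude recovery through the full XIC pipeline at zero noise."""
    raw, peptides, truth = gen_phospho_raw(PhosphoSimParams(n_peptides=n_peptides, seed=seed))
    matrix = quantify(raw, peptides, XICParams())
    amp_cols = [c for c in truth.columns if c.startswith("amp_")]
    planted = truth[amp_cols].to_numpy()
    recovered = matrix.heights[[c.replace("amp_", "") for c in amp_cols]].to_numpy()
    rel = np.abs(recovered - planted) / planted
    return {
        "frac_within_2pct": float(np.mean(np.nanmax(rel, axis=1) <= 0.02)),
        "max_rel_err_pct": float(100.0 * np.nanmax(rel)),
        "n_peptides": n_peptides,
    }


def phospho_null_calibration(n_peptides: int = 2000, seed: int = 0) -> dict[str, float]:
    """Raw-p false-positive rate with no regulation planted (type-I control)."""
    raw, peptides, _ = gen_phospho_raw(
        PhosphoSimParams(n_peptides=n_peptides, noise_sd_log2=0.25, seed=seed)
    )
    matrix = normalize_heights(
        quantify(raw, peptides, conditions={s: s[0] for s in raw.samples()})
    )
    p = np.array([r.p for r in differential(matrix, "A", "B")])
    return {
        "null_frac_p_lt_05": float(np.mean(p[np.isfinite(p)] < 0.05)),
        "n_peptides": n_peptides,
    }


def _ksea_sim_params(seed: int, regulated: bool) -> PhosphoSimParams:
    return PhosphoSimParams(
        n_peptides=1000,
        fraction_regulated=0.03 if regulated else 0.0,
        planted_log2fc=1.0,
        planted_kinases=[("K_PLANTED", 30)] if regulated else [],
        n_decoy_kinases=51 if not regulated else 50,
        substrates_per_decoy=30 if not regulated else 15,
        noise_sd_log2=0.1,
        seed=seed,
    )


def ksea_recovery(n_sims: int = 100, seed: int = 0) -> dict[str, float]:
    """How often the planted kinase ranks first by p among >=50 decoys."""
    wins = 0
    for i in range(n_sims):
        matrix, truth = gen_phospho_matrix(_ksea_sim_params(seed + i, regulated=True))
        diff = differential_table(differential(matrix, "A", "B"))
        rows = ksea(diff, kinase_setdb(truth))
        best = min(rows, key=lambda r: (r.p, r.set_name))
        wins += best.set_name == "K_PLANTED"
    return {"rank_first_frac": wins / n_sims, "n_sims": n_sims}


def ksea_null_uniformity(n_sims: int = 500, seed: int = 0) -> dict[str, float]:
    """KS uniformity of randomized-PIT KSEA p-values under permuted labels.

    Labels are permuted on unregulated data, and one 30-substrate kinase's
    up-direction randomized p (P[X>k] + U P[X=k]) is collected per
    simulation; a correctly computed null CDF makes these exactly uniform.
    """
    rng = np.random.default_rng(seed)
    pvals = []
    for i in range(n_sims):
        matrix, truth = gen_phospho_matrix(_ksea_sim_params(seed + 10_000 + i, regulated=False))
        perm = rng.permutation(matrix.conditions.to_numpy())
        matrix.conditions = pd.Series(perm, index=matrix.conditions.index)
        diff = differential_table(differential(matrix, "A", "B"))
        rows = ksea(diff, kinase_setdb(truth), p_mode="randomized", rng=rng)
        row = next(r for r in rows if r.set_name == "DECOY_K1" and r.direction == "up")
        pvals.append(row.p)
    ks = sps.kstest(np.asarray(pvals), "uniform")
    return {
        "ks_statistic": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "n_sims": n_sims,
    }


def silac_coregulation_recovery(seed: int = 0) -> dict[str, float]:
    """Sensitivity/precision of the co-down call at 50% planted co-regulation."""
    params = SilacSimParams(fraction_co_down=0.5, noise_sd_log2=0.1, seed=seed)
    table, _, truth = gen_silac_table(params)
    filtered, _ = filter_records(table)
    result = cross_coregulation(log2_normalize(filtered))
    true_down = set(truth.loc[truth["co_down_true"], "protein_id"]) & set(
        filtered["protein_id"]
    )
    tp = len(result.co_down & true_down)
    return {
        "sensitivity": tp / len(true_down) if true_down else float("nan"),
        "precision": tp / len(result.co_down) if result.co_down else float("nan"),
        "n_true_co_down": len(true_down),
    }


def silac_pathway_detection(n_sims: int = 100, seed: int = 0) -> dict[str, float]:
    """How often the planted pathway makes the q<=0.05, enrichment>2 report."""
    hits = 0
    for i in range(n_sims):
        table, db, _ = gen_silac_table(SilacSimParams(seed=seed + i))
        filtered, _ = filter_records(table)
        result = cross_coregulation(log2_normalize(filtered))
        report, _ = pathway_report(result.co_down, filtered["protein_id"], db)
        hits += "PLANTED_DOWN_1" in set(report["pathway"])
    return {"pathway_detection_frac": hits / n_sims, "n_sims": n_sims}
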
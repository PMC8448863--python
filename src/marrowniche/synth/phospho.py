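"""Synthetic phosphoproteomic raw data with known quantitative ground truth.

Each identified peptide is given a Gaussian elution peak ~30 s wide at the
base, sampled with at least ten MS1 points, at its theoretical m/z with
ppm-level jitter — the structure XIC peak-height quantification assumes. A
chosen fraction of peptides is regulated between the two conditions with a
planted log2 fold change, and regulated peptides can be assigned to planted
kinase substrate sets alongside decoy kinases, giving an exact oracle for the
differential and kinase-enrichment stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..enrich import SetDB
from ..phospho import IntensityMatrix, RawIonMap

__all__ = ["PhosphoSimParams", "gen_phospho_raw", "gen_phospho_matrix", "kinase_setdb"]


@dataclass
class PhosphoSimParams:
    n_peptides: int = 200
    n_samples_per_condition: int = 3
    peak_width_s: float = 30.0        # full width at base (~4 sigma)
    points_per_peak: int = 12
    mz_jitter_ppm: float = 2.0
    fraction_regulated: float = 0.0
    planted_log2fc: float = 1.0
    planted_kinases: list[tuple[str, int]] = field(default_factory=list)
    n_decoy_kinases: int = 0
    substrates_per_decoy: int = 15
    noise_sd_log2: float = 0.0        # between-sample lognormal amplitude noise
    point_noise_frac: float = 0.0     # multiplicative noise on individual points
    base_amplitude: float = 1e6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.points_per_peak < 2:
            raise ValueError("points_per_peak must be >= 2")
        if not 0.0 <= self.fraction_regulated <= 1.0:
            raise ValueError("fraction_regulated must lie in [0, 1]")
        if self.n_peptides <= 0:
            raise ValueError("n_peptides must be positive")
        if self.n_samples_per_condition < 1:
            raise ValueError("n_samples_per_condition must be >= 1")
        needed = sum(k for _, k in self.planted_kinases)
        if needed > int(round(self.fraction_regulated * self.n_peptides)):
            raise ValueError(
                "planted kinase substrates exceed the number of regulated peptides"
            )


def _truth_frame(params: PhosphoSimParams, rng: np.random.Generator) -> pd.DataFrame:
    n = params.n_peptides
    n_reg = int(round(params.fraction_regulated * n))
    regulated = np.zeros(n, dtype=bool)
    regulated[:n_reg] = True
    kinase = np.array([""] * n, dtype=object)
    pos = 0
    for name, size in params.planted_kinases:
        kinase[pos : pos + size] = name
        pos += size
    # decoy kinases draw substrates from unregulated peptides
    unreg_idx = np.flatnonzero(~regulated)
    for d in range(params.n_decoy_kinases):
        size = min(params.substrates_per_decoy, len(unreg_idx))
        chosen = rng.choice(unreg_idx, size=size, replace=False)
        name = f"DECOY_K{d + 1}"
        for i in chosen:
            kinase[i] = (kinase[i] + ";" + name).lstrip(";")
    ids = np.array([f"pep{i:05d}" for i in range(n)])
    mz = rng.uniform(400.0, 1200.0, size=n)
    rt = rng.uniform(300.0, 3300.0, size=n)
    charge = rng.integers(2, 4, size=n)
    true_fc = np.where(regulated, params.planted_log2fc, 0.0)
    return pd.DataFrame(
        {
            "peptide_id": ids,
            "mz": mz,
            "charge": charge,
            "rt_apex_s": rt,
            "site": [f"PROT{i % 997}_S{i % 61 + 1}" for i in range(n)],
            "regulated": regulated,
            "true_log2fc": true_fc,
            "kinases": kinase,
            "base_amplitude": np.full(n, params.base_amplitude),
        }
    )


def _sample_names(params: PhosphoSimParams) -> tuple[list[str], dict[str, str]]:
    names, cond = [], {}
    for c in ("A", "B"):
        for r in range(params.n_samples_per_condition):
            s = f"{c}{r + 1}"
            names.append(s)
            cond[s] = c
    return names, cond


def _amplitudes(truth: pd.DataFrame, params: PhosphoSimParams, rng: np.random.Generator) -> pd.DataFrame:
    """Per-peptide per-sample planted amplitudes (condition B carries the fold change)."""
    names, cond = _sample_names(params)
    base = truth["base_amplitude"].to_numpy()
    fc = truth["true_log2fc"].to_numpy()
    out = {}
    for s in names:
        mean = base * (2.0**fc if cond[s] == "B" else 1.0)
        if params.noise_sd_log2 > 0:
            mean = mean * 2.0 ** rng.normal(0.0, params.noise_sd_log2, size=len(base))
        out[s] = mean
    return pd.DataFrame(out, index=truth["peptide_id"].to_numpy())


def gen_phospho_raw(params: PhosphoSimParams) -> tuple[RawIonMap, pd.DataFrame, pd.DataFrame]:
    """Generate (raw ion map, peptide identification table, truth table).

    Each peptide contributes a Gaussian elution profile per sample: one point
    sits exactly at the apex, the rest at fixed spacing covering the peak
    base, so with zero noise the apex intensity equals the planted amplitude
    exactly. The truth table carries per-sample amplitudes as
    ``amp_<sample>`` columns plus the regulated flag and kinase annotation.
    """
    rng = np.random.default_rng(params.seed)
    truth = _truth_frame(params, rng)
    amps = _amplitudes(truth, params, rng)
    names, _ = _sample_names(params)

    npts = params.points_per_peak
    spacing = params.peak_width_s / npts
    sigma = params.peak_width_s / 4.0  # base width ~ 4 sigma
    offsets = spacing * (np.arange(npts) - npts // 2)
    profile = np.exp(-(offsets**2) / (2.0 * sigma**2))

    n = params.n_peptides
    mz0 = truth["mz"].to_numpy()
    rt0 = truth["rt_apex_s"].to_numpy()
    frames = []
    for s in names:
        a = amps[s].to_numpy()
        inten = (a[:, None] * profile[None, :]).ravel()
        if params.point_noise_frac > 0:
            inten = inten * (1.0 + rng.normal(0.0, params.point_noise_frac, size=inten.shape))
            inten = np.maximum(inten, 0.0)
        jitter = rng.normal(0.0, params.mz_jitter_ppm / 3.0, size=(n, npts))
        jitter = np.clip(jitter, -params.mz_jitter_ppm, params.mz_jitter_ppm)
        mz = (mz0[:, None] * (1.0 + jitter * 1e-6)).ravel()
        rt = (rt0[:, None] + offsets[None, :]).ravel()
        frames.append(
            pd.DataFrame({"sample": s, "rt_s": rt, "mz": mz, "intensity": inten})
        )
    points = pd.concat(frames, ignore_index=True)

    for s in names:
        truth[f"amp_{s}"] = amps[s].to_numpy()
    peptides = truth[["peptide_id", "mz", "charge", "rt_apex_s", "site"]].copy()
    return RawIonMap(points=points), peptides, truth


def gen_phospho_matrix(params: PhosphoSimParams) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Amplitude-level shortcut: the peptide x sample intensity matrix directly.

    Statistically identical to running the full ion-map emulation through
    noiseless XIC extraction; used for many-replicate enrichment simulations
    where the chromatographic layer (verified separately) would dominate
    runtime.
    """
    rng = np.random.default_rng(params.seed)
    truth = _truth_frame(params, rng)
    amps = _amplitudes(truth, params, rng)
    names, cond = _sample_names(params)
    for s in names:
        truth[f"amp_{s}"] = amps[s].to_numpy()
    matrix = IntensityMatrix(heights=amps, conditions=pd.Series(cond))
    matrix.heights.index.name = "peptide_id"
    return matrix, truth


def kinase_setdb(truth: pd.DataFrame) -> SetDB:
    """Kinase -> substrate-peptide sets from the truth table's annotation column."""
    sets: dict[str, set] = {}
    for pep, anno in zip(truth["peptide_id"], truth["kinases"]):
        if not anno:
            continue
        for kin in str(anno).split(";"):
            sets.setdefault(kin, set()).add(pep)
    return SetDB(sets={k: frozenset(v) for k, v in sets.items()})
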
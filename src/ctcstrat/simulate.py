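"""Synthetic cohort generator.

Emulates the statistical structure of a DEPArray-sorted metastatic breast
cancer cohort: ~45 patients, ~2,600 cells split between eCTC, CD45-positive
leukocytes and other circulating classes, right-skewed feature distributions
(log-normal morphology, gamma intensities) with patient-level random
effects, and right-censored overall survival with a 30-month median.

Prognostic signal is planted at the *patient* level, because the analysis
operates on per-patient aggregates:

* overall survival — patients who die within the median horizon carry more
  circular cells (brightfield circularity shifted by ``effect_os_circularity``
  between-patient standard deviations);
* bone metastasis — BM-positive patients carry bigger cells (brightfield
  log-diameter shifted by ``effect_bm_diameter`` between-patient SDs), a
  size effect that physically propagates to the perimeter as well.

No distributional parameters for real DEPArray features are published; the
defaults here are fixed, documented choices (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import reference
from .cohort import CellRecord, ClinicalRecord, Cohort, assemble_cohort
from .errors import ConfigError
from .vocab import CHANNELS, FLUOR_CHANNELS, CellClass

_CLASSES = (CellClass.ECTC, CellClass.CD45POS, CellClass.OTHER)

# Baseline membrane irregularity z = 1 - circularity, per channel.
_Z0 = {"brightfield": 0.15, "dapi": 0.10, "fitc": 0.16, "pe": 0.16, "apc": 0.14}
# Class multipliers on z: leukocytes are rounder, tumor cells more irregular.
_Z_CLASS = {CellClass.ECTC: 1.3, CellClass.CD45POS: 0.6, CellClass.OTHER: 1.0}
# Cell diameter (um) per class; nuclei (dapi) are smaller than the cell body.
_DIAM_CLASS = {CellClass.ECTC: 16.0, CellClass.CD45POS: 10.0, CellClass.OTHER: 12.0}
_DIAM_CHANNEL = {"brightfield": 1.0, "dapi": 0.65, "fitc": 0.95, "pe": 0.95, "apc": 0.95}
# Mean fluorescence intensity (a.u.) per class x channel: eCTC express
# epithelial markers (FITC), leukocytes CD45 (APC), all nuclei stain (DAPI).
_INTENSITY = {
    CellClass.ECTC:    {"brightfield": 500.0, "dapi": 800.0, "fitc": 600.0, "pe": 100.0, "apc": 40.0},
    CellClass.CD45POS: {"brightfield": 500.0, "dapi": 800.0, "fitc": 60.0, "pe": 150.0, "apc": 700.0},
    CellClass.OTHER:   {"brightfield": 500.0, "dapi": 800.0, "fitc": 80.0, "pe": 300.0, "apc": 50.0},
}

# Between-patient (tau) and within-patient (sigma) spreads, log scale.
_TAU_Z, _SIG_Z = 0.35, 0.35
_TAU_D, _SIG_D = 0.12, 0.15
_TAU_I = 0.30
_SIG_PERIM = 0.08

#: Channel carrying the planted overall-survival circularity effect.
OS_PLANT_CHANNEL = "brightfield"
#: Channel carrying the planted bone-metastasis size effect.
BM_PLANT_CHANNEL = "brightfield"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    ``effect_os_circularity`` and ``effect_bm_diameter`` are standardized
    shifts *d* of the patient-level latent mean between outcome classes, in
    units of the between-patient SD.
    """

    n_patients: int = 45
    cells_per_patient_mean: float = reference.TOTAL_CELLS / 45
    cells_per_patient_dispersion: float = 2.0  # negative-binomial shape
    class_mix: tuple[float, float, float] = field(
        default_factory=reference.reference_class_mix
    )  # (eCTC, CD45pos, other)
    class_mix_concentration: float = 4.0  # Dirichlet scale; lower = more 0-eCTC patients
    effect_os_circularity: float = 2.0
    effect_bm_diameter: float = 2.0
    bone_met_prevalence: float = reference.BONE_MET_PREVALENCE
    censor_fraction: float = 0.2
    survival_median_months: float = 30.0
    survival_log_sd: float = 0.9
    seed: int = 0

    def validate(self) -> None:
        mix = np.asarray(self.class_mix, float)
        if mix.shape != (3,) or (mix < 0).any() or abs(mix.sum() - 1.0) > 1e-6:
            raise ConfigError(f"class_mix {self.class_mix} must be 3 non-negative fractions summing to 1")
        if mix[0] == 0 and mix[1] == 0:
            raise ConfigError("class_mix assigns zero mass to both eCTC and CD45pos")
        if self.effect_os_circularity < 0 or self.effect_bm_diameter < 0:
            raise ConfigError("planted effect sizes must be >= 0")
        if not (0 <= self.censor_fraction < 1):
            raise ConfigError("censor_fraction must lie in [0, 1)")
        if self.n_patients < 2 or self.cells_per_patient_mean <= 0:
            raise ConfigError("need n_patients >= 2 and a positive cell count mean")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def _censoring_horizon(times: np.ndarray, fraction: float) -> float:
    """Upper bound c of Uniform(0, c) censoring with E[censored] ~= fraction.

    Censoring is independent of survival; P(C < T) = E[min(T, c)] / c, which
    decreases in c, so the horizon is found by bisection on the drawn times.
    """
    lo, hi = 1e-6, float(times.max()) * 1e4
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if np.minimum(times, mid).mean() / mid > fraction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(config: SimConfig) -> Cohort:
    """Draw one synthetic cohort; byte-identical under a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    pids = [f"P{i + 1:02d}" for i in range(n)]

    # --- outcomes -------------------------------------------------------
    t_true = config.survival_median_months * np.exp(
        rng.normal(0.0, config.survival_log_sd, n)
    )
    os_long = t_true > config.survival_median_months  # survived past the horizon
    bone_met = rng.random(n) < config.bone_met_prevalence
    if config.censor_fraction > 0:
        c_max = _censoring_horizon(t_true, config.censor_fraction)
        c = rng.uniform(0.0, c_max, n)
        os_event = t_true <= c
        os_months = np.minimum(t_true, c)
    else:
        os_event = np.ones(n, bool)
        os_months = t_true

    # --- cohort composition --------------------------------------------
    r = config.cells_per_patient_dispersion
    p = r / (r + config.cells_per_patient_mean)
    n_cells = np.maximum(1, rng.negative_binomial(r, p, n))
    mix = np.asarray(config.class_mix, float)
    props = rng.dirichlet(np.maximum(mix * config.class_mix_concentration, 1e-9), n)
    pat_idx = np.repeat(np.arange(n), n_cells)
    m = pat_idx.size
    u = rng.random(m)
    cls_idx = (u[:, None] > np.cumsum(props[pat_idx], axis=1)).sum(axis=1)
    cls_idx = np.minimum(cls_idx, 2)

    # --- patient-level latents with planted effects ---------------------
    d_os = config.effect_os_circularity
    d_bm = config.effect_bm_diameter
    # sign convention: short survivors -> lower z (rounder cells)
    os_shift = np.where(os_long, +0.5, -0.5) * d_os * _TAU_Z
    bm_shift = np.where(bone_met, +0.5, -0.5) * d_bm * _TAU_D

    features: dict[str, np.ndarray] = {}
    z_class = np.array([np.log(_Z_CLASS[c]) for c in _CLASSES])[cls_idx]
    diam_class = np.array([np.log(_DIAM_CLASS[c]) for c in _CLASSES])[cls_idx]

    for ch in CHANNELS:
        for par, z0_scale in (("circularity", 1.0), ("circularityOV", 0.8)):
            eps = rng.normal(0.0, _TAU_Z, n)
            if par == "circularity" and ch == OS_PLANT_CHANNEL:
                eps = eps + os_shift
            mu = np.log(_Z0[ch] * z0_scale) + z_class + eps[pat_idx]
            z = np.exp(rng.normal(mu, _SIG_Z))
            features[f"{par}_{ch}"] = 1.0 - np.minimum(z, 0.995)

        eps_d = rng.normal(0.0, _TAU_D, n)
        if ch == BM_PLANT_CHANNEL:
            eps_d = eps_d + bm_shift
        mu_d = diam_class + np.log(_DIAM_CHANNEL[ch]) + eps_d[pat_idx]
        diam = np.exp(rng.normal(mu_d, _SIG_D))
        features[f"diameter_{ch}"] = diam
        features[f"perimeter_{ch}"] = (
            np.pi * diam / np.sqrt(features[f"circularity_{ch}"])
            * np.exp(rng.normal(0.0, _SIG_PERIM, m))
        )

        base = np.array([_INTENSITY[c][ch] for c in _CLASSES])[cls_idx]
        mult = np.exp(rng.normal(0.0, _TAU_I, n))[pat_idx]
        mean_int = rng.gamma(4.0, base * mult / 4.0)
        features[f"mean_intensity_{ch}"] = mean_int
        features[f"max_intensity_{ch}"] = mean_int * (1.0 + rng.gamma(2.0, 0.3, m))
        if ch in FLUOR_CHANNELS:
            features[f"mean_intensity_bgsub_{ch}"] = mean_int * rng.beta(8.0, 2.0, m)

    # --- assemble records ----------------------------------------------
    cells: list[CellRecord] = []
    counter = np.zeros(n, int)
    feat_names = list(features)
    cols = [features[k] for k in feat_names]
    for j in range(m):
        pi = pat_idx[j]
        counter[pi] += 1
        cells.append(
            CellRecord(
                patient_id=pids[pi],
                cell_id=f"{pids[pi]}_c{counter[pi]:03d}",
                cell_class=_CLASSES[cls_idx[j]],
                features={k: float(col[j]) for k, col in zip(feat_names, cols)},
            )
        )
    clinical = [
        ClinicalRecord(
            patient_id=pids[i],
            os_months=float(np.round(os_months[i], 2)),
            os_event=bool(os_event[i]),
            bone_met=bool(bone_met[i]),
        )
        for i in range(n)
    ]
    return assemble_cohort(cells, clinical)
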
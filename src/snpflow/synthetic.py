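"""Seeded synthetic longitudinal cohorts with TADPOLE-like structure.

Each simulated patient carries a latent disease severity that starts at a
random baseline and increases monotonically at a patient-specific rate
(AR(1)-correlated positive increments), crossing two fixed thresholds that
define the ordinal CN -> MCI -> AD stages. Observed features are affine in
severity — cognitive burden scores (CDRSB, ADAS, FAQ) and ventricular
volume rise with severity, while MMSE, RAVLT and the remaining regional
brain volumes fall — plus independent Gaussian noise scaled to each
feature's slope magnitude. An optional second, sign-flipped "mode" of
feature loadings (``multimodal_mix``) makes the feature distribution at
fixed severity bimodal, emulating one-to-many context/target structure.
Missingness is applied completely at random. Everything is deterministic
given the seed.

The simulator is deliberately the simplest process exhibiting temporal
dependence, inter-patient heterogeneity, ordinal stage progression and
optional multimodality; it makes no attempt at biophysical realism or at
matching real TADPOLE marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Dict, List, Tuple

import numpy as np

from .windows_io import FEATURE_COLUMNS, VisitRecord, write_visits

# Per-feature affine maps from latent severity to native units:
# intercept = healthy (severity 0) level, slope = change per severity unit.
# Signs follow the instruments: burden scores and Ventricles increase,
# MMSE/RAVLT and the other volumes decrease.
DEFAULT_INTERCEPTS = np.array([
    0.5,        # CDRSB
    6.0,        # ADAS11
    9.0,        # ADAS13
    29.0,       # MMSE
    42.0,       # RAVLT_immediate
    0.5,        # FAQ
    30000.0,    # Ventricles
    7200.0,     # Hippocampus
    1050000.0,  # WholeBrain
    3800.0,     # Entorhinal
    20000.0,    # MidTemp
])

DEFAULT_LOADINGS = np.array([
    2.2,        # CDRSB
    4.5,        # ADAS11
    5.5,        # ADAS13
    -2.5,       # MMSE
    -6.0,       # RAVLT_immediate
    4.0,        # FAQ
    4000.0,     # Ventricles
    -600.0,     # Hippocampus
    -30000.0,   # WholeBrain
    -350.0,     # Entorhinal
    -1500.0,    # MidTemp
])


@dataclass
class CohortSpec:
    """Simulation parameters; the defaults define the package's study conditions."""

    n_patients: int = 200
    visits_min: int = 5
    visits_max: int = 8
    n_features: int = 11
    progression_rate_mean: float = 0.45
    progression_rate_sd: float = 0.25
    stage_thresholds: Tuple[float, float] = (1.2, 2.6)
    feature_loadings: np.ndarray = field(default_factory=lambda: DEFAULT_LOADINGS.copy())
    feature_intercepts: np.ndarray = field(default_factory=lambda: DEFAULT_INTERCEPTS.copy())
    noise_sd: float = 0.35
    multimodal_mix: float = 0.0
    missing_rate: float = 0.0
    ar_coef: float = 0.5
    ar_sd: float = 0.25
    baseline_severity_max: float = 2.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.visits_min > self.visits_max or self.visits_min < 1:
            raise ValueError("need 1 <= visits_min <= visits_max")
        if not self.stage_thresholds[0] < self.stage_thresholds[1]:
            raise ValueError("stage_thresholds must be strictly increasing")
        if not 0.0 <= self.multimodal_mix <= 1.0:
            raise ValueError("multimodal_mix must be in [0, 1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.feature_loadings) != self.n_features:
            raise ValueError("feature_loadings length must equal n_features")


@dataclass
class GroundTruth:
    """Latent state behind a simulated cohort."""

    rates: Dict[str, float]
    modes: Dict[str, int]                  # +1 canonical, -1 sign-flipped
    severities: Dict[str, np.ndarray]      # per-visit latent severity
    stages: Dict[str, np.ndarray]          # per-visit true ordinal stage


def _stage(severity: np.ndarray, thresholds: Tuple[float, float]) -> np.ndarray:
    """Ordinal stage = number of thresholds the severity has crossed."""
    return (severity[:, None] >= np.asarray(thresholds)[None, :]).sum(axis=1)


def simulate_cohort(spec: CohortSpec) -> Tuple[List[VisitRecord], GroundTruth]:
    """Draw a full cohort; see the module docstring for the generative process."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    loadings = np.asarray(spec.feature_loadings, dtype=np.float64)
    intercepts = np.asarray(spec.feature_intercepts, dtype=np.float64)
    noise_scale = spec.noise_sd * np.abs(loadings)

    visits: List[VisitRecord] = []
    gt = GroundTruth(rates={}, modes={}, severities={}, stages={})
    for p in range(spec.n_patients):
        pid = f"P{p:05d}"
        rate = max(0.0, rng.normal(spec.progression_rate_mean, spec.progression_rate_sd))
        mode = -1 if rng.random() < spec.multimodal_mix else 1
        n_visits = int(rng.integers(spec.visits_min, spec.visits_max + 1))
        baseline = rng.uniform(0.0, spec.baseline_severity_max)

        # Monotone severity: positive AR(1)-modulated increments of mean ~= rate.
        sev = np.empty(n_visits)
        sev[0] = baseline
        ar = 0.0
        for t in range(1, n_visits):
            ar = spec.ar_coef * ar + spec.ar_sd * rng.standard_normal()
            sev[t] = sev[t - 1] + rate * np.exp(ar)
        stages = _stage(sev, spec.stage_thresholds)

        X = intercepts[None, :] + mode * loadings[None, :] * sev[:, None]
        if spec.noise_sd > 0:
            X = X + rng.standard_normal(X.shape) * noise_scale[None, :]
        if spec.missing_rate > 0:
            X[rng.random(X.shape) < spec.missing_rate] = np.nan

        start = date(2005, 1, 1) + timedelta(days=int(rng.integers(0, 3 * 365)))
        for t in range(n_visits):
            d = start + timedelta(days=int(183 * t + rng.integers(0, 30)))
            visits.append(VisitRecord(pid, d, X[t], int(stages[t])))

        gt.rates[pid] = rate
        gt.modes[pid] = mode
        gt.severities[pid] = sev
        gt.stages[pid] = stages
    return visits, gt


def write_cohort(visits: List[VisitRecord], path) -> None:
    """Write a simulated cohort in the exact CSV dialect windows_io reads."""
    write_visits(visits, path)


def last_labels(visits: List[VisitRecord]) -> Dict[str, int]:
    """Each patient's last observed label (used to stratify the split)."""
    out: Dict[str, int] = {}
    seen: Dict[str, date] = {}
    for v in visits:
        if v.patient_id not in seen or v.exam_date > seen[v.patient_id]:
            seen[v.patient_id] = v.exam_date
            out[v.patient_id] = v.label
    return out
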
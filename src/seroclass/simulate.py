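"""Seeded synthetic serum-spectrum cohort generator.

Real patient sera behind the profiling workflow are not publicly
deposited, so simulated cohorts emulate the data's shape: triplicate
unit-mass spectra over m/z 400-2000, log-normal peak intensities with
multiplicative replicate noise, a configurable number of planted
group-discriminatory peaks at a chosen standardized between-group shift,
and demographic covariates (sex, age) drawn to match the study-like
group compositions.

The intensity model: each signal-carrying bin j has a bin-level baseline
log-intensity mu_j ~ Normal(baseline_log_mean, baseline_log_sd), shared
by both groups. A sample's true log-intensity at bin j is
mu_j + delta_j + eps, with eps ~ Normal(0, sample_log_sd) the
between-sample biological variation and delta_j = effect_delta *
sample_log_sd for planted bins in group A (0 otherwise) — i.e. the
planted shift is ``effect_delta`` between-sample standard deviations on
the log scale. Each replicate multiplies the sample truth by log-normal
noise of coefficient of variation ``replicate_cv``. Signal bins are laid
out with a minimum spacing of two m/z units so that valley-to-valley
centroiding resolves each as its own peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .loocv import Cohort, SampleRecord
from .preprocess import (
    DEFAULT_MZ_HI,
    DEFAULT_MZ_LO,
    ReplicateSpectrum,
    ValidationError,
    preprocess_replicates,
)


@dataclass
class SynthParams:
    """Parameters of one simulated binary cohort."""

    n_A: int = 15
    n_B: int = 14
    label_A: str = "mildAD"
    label_B: str = "control"
    mz_lo: int = DEFAULT_MZ_LO
    mz_hi: int = DEFAULT_MZ_HI
    n_discriminatory: int = 100
    effect_delta: float = 2.0
    baseline_log_mean: float = 2.0
    baseline_log_sd: float = 1.0
    sample_log_sd: float = 0.4
    replicate_cv: float = 0.15
    peak_density: float = 0.2
    n_replicates: int = 3
    #: (fraction of males, age low, age high) per group, study-like defaults
    sex_age_A: tuple[float, float, float] = (5 / 15, 56.0, 90.0)
    sex_age_B: tuple[float, float, float] = (7 / 14, 59.0, 84.0)
    seed: int = 0

    def __post_init__(self):
        if self.effect_delta < 0 or self.replicate_cv < 0:
            raise ValidationError("effect_delta and replicate_cv must be >= 0")
        if not (0 < self.peak_density <= 1):
            raise ValidationError("peak_density must be in (0, 1]")
        n_bins = self.mz_hi - self.mz_lo + 1
        n_signal = max(1, int(round(self.peak_density * n_bins)))
        n_slots = len(range(self.mz_lo + 1, self.mz_hi, 3))
        if n_signal > n_slots:
            raise ValidationError(
                f"peak_density {self.peak_density} needs {n_signal} isolated bins, "
                f"only {n_slots} slots available"
            )
        if self.n_discriminatory > n_signal:
            raise ValidationError(
                "n_discriminatory exceeds the number of signal-carrying bins"
            )


@dataclass
class SimulatedCohort:
    """Replicate spectra plus sample metadata for one simulated cohort."""

    params: SynthParams
    replicates: list[ReplicateSpectrum]
    metadata: pd.DataFrame  # sample_id, group, sex, age
    signal_mz: np.ndarray
    planted_mz: np.ndarray

    def to_cohort(self) -> Cohort:
        """Run the preprocessing chain and assemble a classification cohort."""
        vectors = preprocess_replicates(self.replicates)
        meta = self.metadata.set_index("sample_id")
        samples = [
            SampleRecord(
                sample_id=sid,
                group=meta.loc[sid, "group"],
                sex=meta.loc[sid, "sex"],
                age=float(meta.loc[sid, "age"]),
                areas=vec,
            )
            for sid, vec in vectors.items()
        ]
        return Cohort(self.params.label_A, self.params.label_B, samples)


def simulate_cohort(params: SynthParams) -> SimulatedCohort:
    """Generate one seeded cohort of triplicate unit-mass spectra.

    Deterministic per ``params.seed``; permuting nothing, same seed gives
    byte-identical output.
    """
    rng = np.random.default_rng(params.seed)
    n_bins = params.mz_hi - params.mz_lo + 1
    n_signal = max(1, int(round(params.peak_density * n_bins)))
    slots = np.arange(params.mz_lo + 1, params.mz_hi, 3)
    signal_mz = np.sort(rng.choice(slots, size=n_signal, replace=False))
    planted_mz = np.sort(rng.choice(signal_mz, size=params.n_discriminatory, replace=False))
    planted_mask = np.isin(signal_mz, planted_mz)

    mu = rng.normal(params.baseline_log_mean, params.baseline_log_sd, size=n_signal)
    shift = params.effect_delta * params.sample_log_sd

    groups = [params.label_A] * params.n_A + [params.label_B] * params.n_B
    sigma_rep = np.sqrt(np.log1p(params.replicate_cv**2))

    replicates: list[ReplicateSpectrum] = []
    meta_rows = []
    for i, group in enumerate(groups):
        sid = f"S{i + 1:03d}"
        frac_m, age_lo, age_hi = params.sex_age_A if group == params.label_A else params.sex_age_B
        sex = "M" if rng.random() < frac_m else "F"
        age = float(rng.uniform(age_lo, age_hi))
        meta_rows.append({"sample_id": sid, "group": group, "sex": sex, "age": age})

        eps = rng.normal(0.0, params.sample_log_sd, size=n_signal)
        log_truth = mu + eps
        if group == params.label_A:
            log_truth = log_truth + shift * planted_mask
        truth = np.exp(log_truth)
        for r in range(1, params.n_replicates + 1):
            noise = np.exp(rng.normal(0.0, sigma_rep, size=n_signal)) if sigma_rep > 0 else 1.0
            intens = np.zeros(n_bins)
            intens[signal_mz - params.mz_lo] = truth * noise
            replicates.append(
                ReplicateSpectrum(sid, r, intens, params.mz_lo, params.mz_hi)
            )

    metadata = pd.DataFrame(meta_rows)
    return SimulatedCohort(params, replicates, metadata, signal_mz, planted_mz)


#: Named parameter presets keyed to the study's group configurations.
_PRESETS: dict[str, SynthParams] = {
    # ion-trap mild AD (n=15) vs control (n=14), strong planted effect
    "mildAD_vs_control_iontrap": SynthParams(),
    # ion-trap moderate AD (n=16) vs control (n=14)
    "moderateAD_vs_control_iontrap": SynthParams(
        n_A=16, label_A="moderateAD", sex_age_A=(7 / 16, 61.0, 88.0)
    ),
    # combined AD (n=31) vs control (n=14)
    "AD_vs_control_iontrap": SynthParams(
        n_A=31, label_A="AD", sex_age_A=(12 / 31, 56.0, 90.0)
    ),
    # label-exchangeable null: no planted group effect
    "null": SynthParams(effect_delta=0.0),
}


def preset(name: str) -> SynthParams:
    """A documented parameter preset by name (a fresh copy)."""
    if name not in _PRESETS:
        raise ValidationError(
            f"unknown preset {name!r}; available: {sorted(_PRESETS)}"
        )
    return replace(_PRESETS[name])


def preset_names() -> list[str]:
    return sorted(_PRESETS)
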
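"""Synthetic cohorts and the deterministic marginal-count fixture.

Two sources of data stand in for the (undeposited) trial records:

* :func:`generate_cohort` draws cohorts from a generative model with the
  structure the analysis assumes — gastric pH elevated by acid
  suppression and recent feeding, a stomach-specific lipase-mediated acid
  shift that applies only to gastric samples under the ester strip, two
  correlated readers on a discretised strip scale, and site-level
  variation in the lipase response.

* :func:`trial_fixture` reconstructs a dataset whose marginal counts at
  the analysis cut-offs equal the published ones exactly, so every
  count-derived headline number is reproducible without data access.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Mapping, Optional

import numpy as np

from .records import (
    PatientDataset,
    PatientRecord,
    ReferenceMethod,
    TubeLocation,
)

__all__ = [
    "CohortParams",
    "FixtureSpec",
    "TRIAL_FIXTURE_SPEC",
    "DEFAULT_SEED",
    "generate_cohort",
    "trial_fixture",
]

#: trial registration date, used as the default stream seed
DEFAULT_SEED = 20170621


@dataclass(frozen=True)
class CohortParams:
    """Generative settings for a synthetic two-gate cohort.

    Latent gastric pH for an unmedicated, fasting patient is
    N(``gastric_ph_mean``, ``gastric_ph_sd``); acid suppression and
    non-fasting add ``medication_shift`` and ``feeding_shift`` pH units.
    The ester strip realises an acid shift max(0, lipase + site effect)
    on gastric samples only.  Lung aspirates are near-neutral and
    identical under both strips.  Readers share the latent strip value
    and differ only by ``reader_sd`` noise before grid snapping.

    Defaults are calibrated so that the pooled sensitivities at cut-off
    5.5 sit near 49.2% (standard) and 70.2% (novel) at the study's
    prevalence of acid suppression (88%) and non-fasting (84%).
    """

    n_gastric: int = 376
    n_lung: int = 38
    n_sites: int = 10
    acid_suppression_prev: float = 0.88
    nonfasting_prev: float = 0.84
    gastric_ph_mean: float = 1.8
    gastric_ph_sd: float = 1.6
    medication_shift: float = 3.1
    feeding_shift: float = 1.2
    lipase_drop_mean: float = 1.0
    lipase_drop_sd: float = 0.5
    lung_ph_mean: float = 7.15
    lung_ph_sd: float = 1.16  # back-solved from the published lung CI half-width
    reader_sd: float = 0.25
    site_effect_sd: float = 0.35
    granularity: float = 0.5
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        for name in ("acid_suppression_prev", "nonfasting_prev"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name}={p} outside [0, 1]")
        for name in (
            "gastric_ph_sd",
            "lipase_drop_sd",
            "lung_ph_sd",
            "reader_sd",
            "site_effect_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_gastric", "n_lung", "n_sites"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_sites == 0 and self.n_gastric > 0:
            raise ValueError("need at least one site for gastric records")
        if self.granularity <= 0:
            raise ValueError("granularity must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, object]) -> "CohortParams":
        unknown = set(mapping) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown cohort parameters: {sorted(unknown)}")
        return cls(**mapping)  # type: ignore[arg-type]


def _snap(values: np.ndarray, step: float) -> np.ndarray:
    """Round to the nearest grid step, ties away from zero."""
    return np.floor(np.abs(values) / step + 0.5) * step * np.sign(values)


def _simulate_arrays(params: CohortParams, rng: np.random.Generator) -> dict:
    """Vectorised draw of all reading arrays; consumed by generate_cohort."""
    p = params
    out: dict = {}

    site_effect = rng.normal(0.0, p.site_effect_sd, size=p.n_sites)

    n = p.n_gastric
    med = rng.random(n) < p.acid_suppression_prev
    nonfast = rng.random(n) < p.nonfasting_prev
    site = rng.integers(0, p.n_sites, size=n) if n else np.zeros(0, dtype=int)
    latent = (
        p.gastric_ph_mean
        + p.medication_shift * med
        + p.feeding_shift * nonfast
        + rng.normal(0.0, p.gastric_ph_sd, size=n)
    )
    drop = np.maximum(0.0, rng.normal(p.lipase_drop_mean, p.lipase_drop_sd, size=n) + site_effect[site])
    std_strip = latent
    novel_strip = latent - drop

    def read(strip_value: np.ndarray) -> np.ndarray:
        noisy = strip_value + rng.normal(0.0, p.reader_sd, size=strip_value.shape)
        return np.clip(_snap(noisy, p.granularity), 0.0, 14.0)

    out["gastric"] = {
        "med": med,
        "nonfast": nonfast,
        "site": site,
        "std_r1": read(std_strip),
        "std_r2": read(std_strip),
        "novel_r1": read(novel_strip),
        "novel_r2": read(novel_strip),
    }

    m = p.n_lung
    lung_latent = rng.normal(p.lung_ph_mean, p.lung_ph_sd, size=m)
    out["lung"] = {
        "std_r1": read(lung_latent),
        "std_r2": read(lung_latent),
        "novel_r1": read(lung_latent),
        "novel_r2": read(lung_latent),
    }
    return out


def generate_cohort(
    params: Optional[CohortParams] = None, seed: Optional[int] = None
) -> PatientDataset:
    """Draw a synthetic two-gate cohort; fully reproducible given a seed."""
    p = params or CohortParams()
    rng = np.random.default_rng(p.seed if seed is None else seed)
    arrays = _simulate_arrays(p, rng)

    records: list[PatientRecord] = []
    g = arrays["gastric"]
    for i in range(p.n_gastric):
        std_avg = (g["std_r1"][i] + g["std_r2"][i]) / 2.0
        records.append(
            PatientRecord(
                patient_id=f"G{i + 1:04d}",
                site_id=f"site{g['site'][i] + 1:02d}",
                true_location=TubeLocation.GASTRIC,
                std_r1=float(g["std_r1"][i]),
                std_r2=float(g["std_r2"][i]),
                novel_r1=float(g["novel_r1"][i]),
                novel_r2=float(g["novel_r2"][i]),
                acid_suppression=bool(g["med"][i]),
                fasting=not bool(g["nonfast"][i]),
                reference_method=(
                    ReferenceMethod.CXR
                    if std_avg > 5.5
                    else ReferenceMethod.CLINICAL_OBSERVATION
                ),
            )
        )
    lu = arrays["lung"]
    for i in range(p.n_lung):
        records.append(
            PatientRecord(
                patient_id=f"L{i + 1:04d}",
                site_id="site01",
                true_location=TubeLocation.LUNG,
                std_r1=float(lu["std_r1"][i]),
                std_r2=float(lu["std_r2"][i]),
                novel_r1=float(lu["novel_r1"][i]),
                novel_r2=float(lu["novel_r2"][i]),
                acid_suppression=False,
                fasting=True,
                reference_method=ReferenceMethod.CAPNOGRAPHY,
            )
        )
    return PatientDataset(tuple(records), granularity=p.granularity)


@dataclass(frozen=True)
class FixtureSpec:
    """Cumulative safe-to-feed counts at the analysis cut-offs.

    ``standard_cumulative``/``novel_cumulative`` map cut-off -> number of
    gastric records reading at or below it; lung bins give the counts at
    the representative lung readings.
    """

    standard_cumulative: Mapping[float, int]
    novel_cumulative: Mapping[float, int]
    n_gastric: int
    lung_bins: Mapping[float, int]
    n_lung: int

    def __post_init__(self) -> None:
        for name, cum in (
            ("standard", self.standard_cumulative),
            ("novel", self.novel_cumulative),
        ):
            prev = 0
            for cutoff in sorted(cum):
                if cum[cutoff] < prev:
                    raise ValueError(f"{name} cumulative counts decrease at {cutoff}")
                prev = cum[cutoff]
            if prev > self.n_gastric:
                raise ValueError(f"{name} counts exceed the gastric total")
        if sum(self.lung_bins.values()) != self.n_lung:
            raise ValueError("lung bin counts must sum to the lung total")
        if any(v < 0 for v in self.lung_bins.values()):
            raise ValueError("negative lung bin count")


#: published marginal counts: cumulative gastric calls at 4.0/5.0/5.5/6.0
#: and the lung readings (four borderline 5.5s, four in (5.5, 6], rest
#: above 6)
TRIAL_FIXTURE_SPEC = FixtureSpec(
    standard_cumulative={4.0: 125, 5.0: 163, 5.5: 185, 6.0: 243},
    novel_cumulative={4.0: 134, 5.0: 211, 5.5: 264, 6.0: 312},
    n_gastric=376,
    lung_bins={5.5: 4, 6.0: 4, 7.0: 30},
    n_lung=38,
)

#: representative strip value for each inter-cutoff bin
_BIN_VALUES = (4.0, 5.0, 5.5, 6.0, 7.0)


def _bin_counts(cumulative: Mapping[float, int], total: int) -> list[int]:
    cuts = sorted(cumulative)
    counts, prev = [], 0
    for c in cuts:
        counts.append(cumulative[c] - prev)
        prev = cumulative[c]
    counts.append(total - prev)
    return counts


def _spread_indices(total: int, k: int) -> set[int]:
    """k indices spread evenly over range(total), deterministic."""
    return {int((j + 0.5) * total / k) for j in range(k)}


def trial_fixture(spec: FixtureSpec = TRIAL_FIXTURE_SPEC) -> PatientDataset:
    """Deterministic dataset reproducing the published marginal counts.

    Gastric readings are placed at bin-representative values so that the
    cumulative counts at the four cut-offs match the spec under both
    strips; the within-patient coupling is comonotonic (both strips'
    values sorted and paired by rank), to which all marginal statistics
    are invariant.  Both readers are set to the strip value.  Covariate
    flags reproduce the published prevalences (330/376 on acid
    suppression, 316/376 not fasting).  Lung records carry novel-strip
    readings only, as in the study.
    """
    std_values: list[float] = []
    for value, count in zip(_BIN_VALUES, _bin_counts(spec.standard_cumulative, spec.n_gastric)):
        std_values.extend([value] * count)
    novel_values: list[float] = []
    for value, count in zip(_BIN_VALUES, _bin_counts(spec.novel_cumulative, spec.n_gastric)):
        novel_values.extend([value] * count)
    std_values.sort()
    novel_values.sort()

    n = spec.n_gastric
    no_med = _spread_indices(n, n - 330) if n == 376 else set()
    fasting = _spread_indices(n, n - 316) if n == 376 else set()

    records: list[PatientRecord] = []
    for i, (s, v) in enumerate(zip(std_values, novel_values)):
        records.append(
            PatientRecord(
                patient_id=f"G{i + 1:04d}",
                site_id=f"site{i % 10 + 1:02d}",
                true_location=TubeLocation.GASTRIC,
                std_r1=s,
                std_r2=s,
                novel_r1=v,
                novel_r2=v,
                acid_suppression=i not in no_med,
                fasting=i in fasting,
                reference_method=(
                    ReferenceMethod.CXR if s > 5.5 else ReferenceMethod.CLINICAL_OBSERVATION
                ),
            )
        )
    j = 0
    for value in sorted(spec.lung_bins):
        for _ in range(spec.lung_bins[value]):
            j += 1
            records.append(
                PatientRecord(
                    patient_id=f"L{j:04d}",
                    site_id="site01",
                    true_location=TubeLocation.LUNG,
                    novel_r1=value,
                    novel_r2=value,
                    acid_suppression=False,
                    fasting=True,
                    reference_method=ReferenceMethod.CAPNOGRAPHY,
                )
            )
    return PatientDataset(tuple(records), granularity=0.5)
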
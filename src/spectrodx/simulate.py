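"""Synthetic serum ATR-FTIR cohort simulator.

Generates spectral cohorts with the replicate structure of a slide-based
serum assay: each patient contributes ``wells_per_patient`` sample wells and
``scans_per_well`` scans per well (default 3 x 3 = 9 spectra per patient).
The spectral model is a sum of Gaussian absorption bands over the
fingerprint region (1800-900 cm^-1), with the cancer class differing only by
a small fractional amplitude shift on a few designated bands, so the two
class means are nearly indistinguishable by eye.  Realistic nuisance
structure is layered on top:

* a random polynomial baseline drawn per well (scatter / drift),
* a multiplicative amplitude scale per well (droplet-thickness effect),
* an additive offset per well (slide positioning),
* independent white noise per scan and per point (detector noise).

Scans from the same well share the well-level draws, so within-well spectra
are more correlated than between-well spectra.

All randomness flows through one :class:`numpy.random.Generator` seeded from
``SimConfig.seed``; an identical configuration reproduces a byte-identical
cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidConfigError

__all__ = [
    "Band",
    "SimConfig",
    "Spectrum",
    "PatientRecord",
    "make_grid",
    "band_profile",
    "simulate_patient",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]

CANCER = "cancer"
NON_CANCER = "non-cancer"

#: Default Gaussian band library: (centre cm^-1, width cm^-1, base amplitude).
#: Centres mimic the dominant serum features of the fingerprint region:
#: amide I (~1650), amide II (~1540), lipid/protein CH bending (~1450),
#: COO- stretch (~1400), amide III / phosphate (~1240), carbohydrate /
#: nucleic-acid backbone (~1080).  Amplitudes are arbitrary absorbance units.
DEFAULT_BANDS: tuple[tuple[float, float, float], ...] = (
    (1650.0, 28.0, 1.00),
    (1540.0, 24.0, 0.70),
    (1450.0, 18.0, 0.35),
    (1400.0, 18.0, 0.30),
    (1240.0, 26.0, 0.25),
    (1080.0, 30.0, 0.30),
)

#: Band centres whose amplitude is shifted in the cancer class.
DEFAULT_CANCER_BANDS: tuple[float, ...] = (1540.0, 1240.0, 1080.0)

#: Tumour-subtype mix among cancers, following the glioblastoma-dominant
#: composition of a symptomatic referral cohort (34 glioblastoma, 16
#: metastatic, 5 meningioma and 12 other tumours out of 67).
DEFAULT_SUBTYPE_MIX: Mapping[str, float] = {
    "glioblastoma": 34 / 67,
    "metastasis": 16 / 67,
    "meningioma": 5 / 67,
    "other": 12 / 67,
}


def make_grid(start: float, stop: float, n_points: int) -> np.ndarray:
    """Return a strictly monotone wavenumber grid of ``n_points`` values.

    The grid runs from ``start`` to ``stop`` inclusive, in that direction
    (descending grids, conventional for FTIR, are allowed).
    """
    if n_points < 2:
        raise InvalidConfigError(f"n_points must be >= 2, got {n_points}")
    if start == stop:
        raise InvalidConfigError("grid start and stop must differ")
    return np.linspace(float(start), float(stop), int(n_points))


@dataclass(frozen=True)
class SimConfig:
    """Full generative-model parameterisation for one synthetic cohort.

    Parameters
    ----------
    n_patients : int
        Cohort size (default 385).
    prevalence : float
        Fraction of patients with cancer, in [0, 1] (default 67/385).
    subtype_mix : mapping
        Tumour subtype -> fraction among cancer patients; must sum to 1.
    grid_start, grid_stop, n_points
        Wavenumber grid; defaults span 1800-900 cm^-1 at ~2 cm^-1 spacing.
    band_library : sequence of (centre, width, amplitude)
        Gaussian bands common to both classes.
    cancer_bands : sequence of centres
        Bands whose amplitude is scaled by ``1 + effect_size`` for cancers.
    effect_size : float
        Dimensionless fractional amplitude shift (default 0.03; the class
        means stay visually indistinguishable).
    noise_additive_sd : float
        Per-point white-noise SD, absorbance units.  The default (0.08,
        i.e. 8% of the tallest band) is deliberately generous: it stands in
        for both detector noise and the unmodelled between-patient
        biological variability of real serum, so that default cohorts are
        hard but learnable rather than trivially separable.
    baseline_order : int
        Degree of the random polynomial baseline drawn per well.
    baseline_amp : float
        Scale of the baseline coefficients, absorbance units.
    mult_scale_sd : float
        SD of the per-well multiplicative amplitude scale (droplet thickness).
    well_effect_sd : float
        SD of the per-well additive offset, absorbance units.
    wells_per_patient, scans_per_well : int
        Replicate structure (defaults 3 and 3, i.e. nine spectra per patient).
    seed : int
        Seed for the single random generator driving the whole cohort.
    """

    n_patients: int = 385
    prevalence: float = 67 / 385
    subtype_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_MIX)
    )
    grid_start: float = 1800.0
    grid_stop: float = 900.0
    n_points: int = 451
    band_library: Sequence[tuple[float, float, float]] = DEFAULT_BANDS
    cancer_bands: Sequence[float] = DEFAULT_CANCER_BANDS
    effect_size: float = 0.03
    noise_additive_sd: float = 0.08
    baseline_order: int = 2
    baseline_amp: float = 0.02
    mult_scale_sd: float = 0.05
    well_effect_sd: float = 0.03
    wells_per_patient: int = 3
    scans_per_well: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise InvalidConfigError(f"n_patients must be >= 1, got {self.n_patients}")
        if not 0.0 <= self.prevalence <= 1.0:
            raise InvalidConfigError(f"prevalence must be in [0,1], got {self.prevalence}")
        total = sum(self.subtype_mix.values())
        if self.subtype_mix and abs(total - 1.0) > 1e-9:
            raise InvalidConfigError(f"subtype_mix fractions sum to {total}, expected 1")
        if any(f < 0 for f in self.subtype_mix.values()):
            raise InvalidConfigError("subtype_mix fractions must be non-negative")
        if self.wells_per_patient < 1 or self.scans_per_well < 1:
            raise InvalidConfigError("wells_per_patient and scans_per_well must be >= 1")
        if self.n_points < 2:
            raise InvalidConfigError(f"n_points must be >= 2, got {self.n_points}")
        if self.grid_start == self.grid_stop:
            raise InvalidConfigError("grid start and stop must differ")
        for sd_name in ("noise_additive_sd", "baseline_amp", "mult_scale_sd", "well_effect_sd"):
            if getattr(self, sd_name) < 0:
                raise InvalidConfigError(f"{sd_name} must be non-negative")
        if self.baseline_order < 0:
            raise InvalidConfigError("baseline_order must be >= 0")

    @property
    def spectra_per_patient(self) -> int:
        return self.wells_per_patient * self.scans_per_well

    def grid(self) -> np.ndarray:
        return make_grid(self.grid_start, self.grid_stop, self.n_points)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["subtype_mix"] = dict(self.subtype_mix)
        d["band_library"] = [list(b) for b in self.band_library]
        d["cancer_bands"] = list(self.cancer_bands)
        return d


@dataclass(frozen=True)
class PatientRecord:
    """Ground truth for one patient."""

    patient_id: str
    true_class: str  # "cancer" | "non-cancer"
    subtype: str | None = None
    cohort: int | None = None

    def __post_init__(self) -> None:
        if self.true_class not in (CANCER, NON_CANCER):
            raise InvalidConfigError(
                f"true_class must be '{CANCER}' or '{NON_CANCER}', got {self.true_class!r}"
            )
        if (self.subtype is None) != (self.true_class == NON_CANCER):
            raise InvalidConfigError(
                f"patient {self.patient_id}: subtype must be set iff true_class is cancer"
            )


@dataclass(frozen=True)
class Spectrum:
    """One absorbance trace keyed by patient, well and scan."""

    patient_id: str
    well: int
    scan: int
    wavenumbers: np.ndarray
    absorbances: np.ndarray

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbances, dtype=float)
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "absorbances", ab)
        if wn.shape != ab.shape or wn.ndim != 1:
            raise InvalidConfigError("wavenumbers and absorbances must be 1-D and equal length")
        d = np.diff(wn)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise InvalidConfigError("wavenumber grid must be strictly monotone")
        if not (np.all(np.isfinite(wn)) and np.all(np.isfinite(ab))):
            raise InvalidConfigError("spectrum contains non-finite values")


def band_profile(grid: np.ndarray, bands: Sequence[tuple[float, float, float]],
                 amp_scale: Mapping[float, float] | None = None) -> np.ndarray:
    """Evaluate a sum of Gaussian bands on ``grid``.

    ``amp_scale`` optionally maps a band centre to a multiplicative factor on
    its amplitude (used for the cancer effect).
    """
    out = np.zeros_like(grid, dtype=float)
    for centre, width, amp in bands:
        if amp_scale is not None:
            amp = amp * amp_scale.get(centre, 1.0)
        out += amp * np.exp(-0.5 * ((grid - centre) / width) ** 2)
    return out


def _class_profile(config: SimConfig, true_class: str) -> np.ndarray:
    scale = None
    if true_class == CANCER:
        scale = {c: 1.0 + config.effect_size for c in config.cancer_bands}
    return band_profile(config.grid(), config.band_library, scale)


def simulate_patient(record: PatientRecord, config: SimConfig,
                     rng: np.random.Generator) -> list[Spectrum]:
    """Draw all replicate spectra for one patient.

    Each spectrum is the class-specific Gaussian band sum, plus a per-well
    additive offset, per-well polynomial baseline, per-well multiplicative
    scale, and per-scan additive white noise.  All three scans of a well
    share that well's draws.
    """
    grid = config.grid()
    clean = _class_profile(config, record.true_class)
    # Baseline polynomials evaluated on a normalised axis for conditioning.
    x = np.linspace(-1.0, 1.0, grid.size)
    spectra: list[Spectrum] = []
    for well in range(1, config.wells_per_patient + 1):
        offset = rng.normal(0.0, config.well_effect_sd)
        coeffs = rng.normal(0.0, config.baseline_amp, size=config.baseline_order + 1)
        baseline = np.polynomial.polynomial.polyval(x, coeffs)
        scale = 1.0 + rng.normal(0.0, config.mult_scale_sd)
        for scan in range(1, config.scans_per_well + 1):
            noise = rng.normal(0.0, config.noise_additive_sd, size=grid.size)
            ab = scale * clean + baseline + offset + noise
            spectra.append(Spectrum(record.patient_id, well, scan, grid, ab))
    return spectra


def _round_half_away(x: float) -> int:
    """Round half away from zero, so prevalence targets like 67/385 are exact."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def _apportion(total: int, fractions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of ``total`` among subtype fractions."""
    names = list(fractions)
    raw = {k: total * fractions[k] for k in names}
    counts = {k: int(math.floor(raw[k])) for k in names}
    short = total - sum(counts.values())
    by_remainder = sorted(names, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in by_remainder[:short]:
        counts[k] += 1
    return counts


def simulate_cohort(config: SimConfig) -> tuple[list[PatientRecord], list[Spectrum]]:
    """Simulate a full cohort: truth records plus all replicate spectra.

    The number of cancer patients is ``round(n_patients * prevalence)``
    (half away from zero); subtypes are apportioned by ``subtype_mix`` with
    largest remainders, then shuffled over the cancer patients.
    """
    rng = np.random.default_rng(config.seed)
    n_cancer = _round_half_away(config.n_patients * config.prevalence)
    n_cancer = min(n_cancer, config.n_patients)

    width = max(4, len(str(config.n_patients)))
    ids = [f"P{i:0{width}d}" for i in range(1, config.n_patients + 1)]
    is_cancer = np.zeros(config.n_patients, dtype=bool)
    is_cancer[:n_cancer] = True
    rng.shuffle(is_cancer)

    mix = dict(config.subtype_mix) or {"unspecified": 1.0}
    counts = _apportion(n_cancer, mix)
    subtype_pool = [s for s, c in counts.items() for _ in range(c)]
    rng.shuffle(subtype_pool)

    records: list[PatientRecord] = []
    it = iter(subtype_pool)
    for pid, cancer in zip(ids, is_cancer):
        if cancer:
            records.append(PatientRecord(pid, CANCER, next(it)))
        else:
            records.append(PatientRecord(pid, NON_CANCER, None))

    spectra: list[Spectrum] = []
    for rec in records:
        spectra.extend(simulate_patient(rec, config, rng))
    return records, spectra


# ---------------------------------------------------------------------------
# Cohort I/O: long-format spectra CSV + truth-table CSV.

SPECTRA_COLUMNS = ["patient_id", "well", "scan", "wavenumber", "absorbance"]
TRUTH_COLUMNS = ["patient_id", "true_class", "subtype", "cohort"]


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "true_class": [r.true_class for r in records],
            "subtype": [r.subtype if r.subtype is not None else "" for r in records],
            "cohort": [r.cohort if r.cohort is not None else "" for r in records],
        }
    )


def spectra_to_frame(spectra: Sequence[Spectrum]) -> pd.DataFrame:
    parts = []
    for s in spectra:
        parts.append(
            pd.DataFrame(
                {
                    "patient_id": s.patient_id,
                    "well": s.well,
                    "scan": s.scan,
                    "wavenumber": s.wavenumbers,
                    "absorbance": s.absorbances,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def write_cohort(records: Sequence[PatientRecord], spectra: Sequence[Spectrum],
                 path: str | Path) -> tuple[Path, Path]:
    """Write ``<path>_spectra.csv`` and ``<path>_truth.csv``; return the paths."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    spectra_path = path.with_name(path.name + "_spectra.csv")
    truth_path = path.with_name(path.name + "_truth.csv")
    spectra_to_frame(spectra).to_csv(spectra_path, index=False, float_format="%.10g")
    records_to_frame(records).to_csv(truth_path, index=False)
    return spectra_path, truth_path


def read_cohort(path: str | Path) -> tuple[list[PatientRecord], list[Spectrum]]:
    """Read a cohort written by :func:`write_cohort`, validating the schemas.

    Raises :class:`FormatError` on missing columns, unknown class tokens, or
    spectra whose patient id is absent from the truth table.
    """
    path = Path(path)
    spectra_path = path.with_name(path.name + "_spectra.csv")
    truth_path = path.with_name(path.name + "_truth.csv")
    truth = pd.read_csv(truth_path, dtype={"patient_id": str}, keep_default_na=False)
    missing = [c for c in TRUTH_COLUMNS if c not in truth.columns]
    if missing:
        raise FormatError(f"truth table missing columns: {missing}")
    long = pd.read_csv(spectra_path, dtype={"patient_id": str})
    missing = [c for c in SPECTRA_COLUMNS if c not in long.columns]
    if missing:
        raise FormatError(f"spectra file missing columns: {missing}")

    records = []
    for row in truth.itertuples(index=False):
        cls = row.true_class
        if cls not in (CANCER, NON_CANCER):
            raise FormatError(
                f"truth table patient {row.patient_id}: unknown class token {cls!r}"
            )
        subtype = row.subtype if row.subtype not in ("", None) else None
        cohort = int(row.cohort) if str(row.cohort) not in ("", "nan") else None
        records.append(PatientRecord(str(row.patient_id), cls, subtype, cohort))

    known = {r.patient_id for r in records}
    orphans = sorted(set(long["patient_id"]) - known)
    if orphans:
        raise FormatError(f"spectra reference patients absent from truth table: {orphans[:5]}")

    spectra = []
    for (pid, well, scan), grp in long.groupby(["patient_id", "well", "scan"], sort=True):
        spectra.append(
            Spectrum(str(pid), int(well), int(scan),
                     grp["wavenumber"].to_numpy(), grp["absorbance"].to_numpy())
        )
    return records, spectra
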
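"""Synthetic NIR spectra with the statistical structure of a cannabis
inflorescence calibration study.

The study's real spectra are not released, so this module generates datasets
that reproduce the *structure* the analysis pipeline assumes: per-analyte
concentration distributions with stated moments, analyte-specific Gaussian
absorption bands superimposed on a smooth background (a Beer-Lambert-style
linear mixing model), per-scan additive baseline offsets and multiplicative
scatter (the distortion classes SNV corrects), white channel noise (what SG
smoothing reduces), and replicate scans to be averaged.  The band positions
and distortion magnitudes are deliberately simple stand-ins, not physically
assigned cannabinoid overtones; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .datasets import (
    ANALYTE_PAIRS,
    DECARBOXYLATION_FACTOR,
    ReferenceTable,
    SpectraSet,
)


@dataclass(frozen=True)
class AnalyteParams:
    """Truncated-normal concentration parameters for one analyte, % w/w."""

    mean: float
    sd: float
    minimum: float
    maximum: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if not (self.minimum <= self.mean <= self.maximum):
            raise ValueError("require minimum <= mean <= maximum")


@dataclass(frozen=True)
class GaussianBand:
    """One absorption band: centre (nm), width (nm, Gaussian sigma) and
    amplitude in absorbance units per % w/w of the analyte."""

    center_nm: float
    width_nm: float
    amplitude: float

    def profile(self, wavelengths: np.ndarray) -> np.ndarray:
        z = (wavelengths - self.center_nm) / self.width_nm
        return self.amplitude * np.exp(-0.5 * z * z)


# Concentration moments of the three total cannabinoids across the study's
# 890 genotypes (min, max, mean, SD in % w/w of dry mass).
DEFAULT_ANALYTE_PARAMS = {
    "total_CBD": AnalyteParams(mean=7.40, sd=5.12, minimum=0.0, maximum=22.16),
    "total_THC": AnalyteParams(mean=2.49, sd=3.88, minimum=0.0, maximum=16.33),
    "total_CBG": AnalyteParams(mean=0.66, sd=1.34, minimum=0.0, maximum=13.76),
}

# Invented band library: two well-separated bands per analyte inside the
# 950-1650 nm window, amplitudes of order 10 mAU per % w/w over a ~0.5 AU
# background -- comparable to first-overtone C-H band strengths in dried
# plant matrices.  Distinct centres keep the mixture identifiable.
DEFAULT_BAND_LIBRARY = {
    "total_CBD": (
        GaussianBand(1200.0, 35.0, 0.012),
        GaussianBand(1440.0, 50.0, 0.008),
    ),
    "total_THC": (
        GaussianBand(1130.0, 30.0, 0.010),
        GaussianBand(1520.0, 45.0, 0.009),
    ),
    "total_CBG": (
        GaussianBand(1040.0, 28.0, 0.011),
        GaussianBand(1340.0, 40.0, 0.007),
    ),
}

#: Fraction of each total carried by the acidic form in fresh inflorescence.
ACIDIC_FRACTION_OF_TOTAL = 0.90


@dataclass(frozen=True)
class SyntheticConfig:
    """Full recipe for one synthetic dataset.

    Defaults mirror the study conditions: 950-1650 nm at 4 nm (176
    channels), 10 replicate scans per sample, concentration moments from the
    890-genotype reference table.  Distortion magnitudes are realistic NIR
    values chosen once: baseline offsets of ~20 mAU SD, multiplicative
    scatter factors log-normal with sigma 0.05, and white noise of 5 mAU SD
    per channel per scan.
    """

    n_samples: int = 890
    n_replicates: int = 10
    wavelength_start_nm: float = 950.0
    wavelength_end_nm: float = 1650.0
    step_nm: float = 4.0
    analyte_params: dict = field(
        default_factory=lambda: dict(DEFAULT_ANALYTE_PARAMS)
    )
    band_library: dict = field(default_factory=lambda: dict(DEFAULT_BAND_LIBRARY))
    baseline_offset_sd: float = 0.02
    scatter_log_sd: float = 0.05
    noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.step_nm <= 0:
            raise ValueError("step_nm must be > 0")
        if self.wavelength_end_nm <= self.wavelength_start_nm:
            raise ValueError("wavelength range must be non-empty")
        for sd in (self.baseline_offset_sd, self.scatter_log_sd, self.noise_sd):
            if sd < 0:
                raise ValueError("distortion SDs must be >= 0")
        if set(self.band_library) != set(self.analyte_params):
            raise ValueError("band_library must cover exactly the analytes")
        lo, hi = self.wavelength_start_nm, self.wavelength_end_nm
        for analyte, bands in self.band_library.items():
            for b in bands:
                if not (lo <= b.center_nm <= hi):
                    raise ValueError(
                        f"band centre {b.center_nm} nm of {analyte} outside "
                        f"[{lo}, {hi}] nm"
                    )

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(round((self.wavelength_end_nm - self.wavelength_start_nm)
                      / self.step_nm)) + 1
        return self.wavelength_start_nm + self.step_nm * np.arange(n)

    @property
    def analytes(self) -> tuple[str, ...]:
        return tuple(self.analyte_params)

    # -- config file round-trip --------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "n_samples": self.n_samples,
            "n_replicates": self.n_replicates,
            "wavelength_start_nm": self.wavelength_start_nm,
            "wavelength_end_nm": self.wavelength_end_nm,
            "step_nm": self.step_nm,
            "baseline_offset_sd": self.baseline_offset_sd,
            "scatter_log_sd": self.scatter_log_sd,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "analytes": {
                name: {
                    "mean": p.mean, "sd": p.sd,
                    "minimum": p.minimum, "maximum": p.maximum,
                    "bands": [
                        {"center_nm": b.center_nm, "width_nm": b.width_nm,
                         "amplitude": b.amplitude}
                        for b in self.band_library[name]
                    ],
                }
                for name, p in self.analyte_params.items()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        analytes = doc.pop("analytes", None)
        kwargs = dict(doc)
        if analytes:
            kwargs["analyte_params"] = {
                name: AnalyteParams(
                    mean=a["mean"], sd=a["sd"],
                    minimum=a["minimum"], maximum=a["maximum"],
                )
                for name, a in analytes.items()
            }
            kwargs["band_library"] = {
                name: tuple(
                    GaussianBand(b["center_nm"], b["width_nm"], b["amplitude"])
                    for b in a["bands"]
                )
                for name, a in analytes.items()
            }
        return cls(**kwargs)


@dataclass
class SyntheticDataset:
    """Generated spectra plus the ground truth needed for recovery tests."""

    config: SyntheticConfig
    spectra: SpectraSet            # K x R x I, replicate scans retained
    reference: ReferenceTable
    true_pure_spectra: pd.DataFrame  # per-analyte unit-concentration profile
    background: np.ndarray
    distortion_log: pd.DataFrame   # per scan: sample_id, replicate, offset, scatter

    def __post_init__(self) -> None:
        if self.spectra.samples != self.reference.samples:
            raise ValueError("spectra and reference sample IDs disagree")
        for name, p in self.config.analyte_params.items():
            col = self.reference.column(name)
            if np.any(col < p.minimum - 1e-12) or np.any(col > p.maximum + 1e-12):
                raise ValueError(f"{name} outside configured bounds")


# ---------------------------------------------------------------------------
# Generation steps
# ---------------------------------------------------------------------------

_MAX_REJECTION_ROUNDS = 1000


def sample_concentrations(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw per-sample total concentrations, % w/w.

    Each analyte is drawn independently from a normal with the configured
    mean and SD, truncated to [min, max] by rejection (clipping would pile
    probability mass onto the bounds and bias recovery tests).  Raises if
    the acceptance rate is so low the bounds are effectively infeasible.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_samples
    out = {}
    for name, p in config.analyte_params.items():
        if p.sd == 0:
            out[name] = np.full(n, p.mean)
            continue
        vals = np.empty(0)
        for _round in range(_MAX_REJECTION_ROUNDS):
            draw = rng.normal(p.mean, p.sd, size=n)
            vals = np.concatenate([vals, draw[(draw >= p.minimum) & (draw <= p.maximum)]])
            if vals.size >= n:
                break
        else:
            raise RuntimeError(
                f"rejection sampling for {name} failed: bounds "
                f"[{p.minimum}, {p.maximum}] reject nearly all draws"
            )
        out[name] = vals[:n]
    ids = [f"S{i:04d}" for i in range(n)]
    return pd.DataFrame(out, index=pd.Index(ids, name="sample_id"))


def pure_spectra(config: SyntheticConfig) -> pd.DataFrame:
    """Unit-concentration absorption profile of each analyte over the grid."""
    wl = config.wavelengths
    cols = {
        name: sum(b.profile(wl) for b in bands)
        for name, bands in config.band_library.items()
    }
    return pd.DataFrame(cols, index=pd.Index(wl, name="wavelength_nm"))


def background_spectrum(config: SyntheticConfig) -> np.ndarray:
    """Fixed smooth background common to every sample.

    A gentle slope plus three strong broad humps mimicking the bulk-matrix
    (cellulose / residual water) contribution that dominates dried plant
    spectra.  The humps sit between the analyte bands: the bulk matrix, not
    the analytes, then dominates each spectrum's channel-wise variance, so
    the SNV scale factor is nearly concentration-independent — the regime in
    which row-wise normalisation corrects scatter without distorting the
    analyte signal.
    """
    wl = config.wavelengths
    u = (wl - wl[0]) / (wl[-1] - wl[0])
    return (
        0.50
        + 0.10 * u
        + 0.30 * np.exp(-0.5 * ((wl - 985.0) / 30.0) ** 2)
        + 0.25 * np.exp(-0.5 * ((wl - 1275.0) / 35.0) ** 2)
        + 0.35 * np.exp(-0.5 * ((wl - 1600.0) / 45.0) ** 2)
    )


def render_spectrum(
    concentrations, config: SyntheticConfig, *, include_background: bool = True
) -> np.ndarray:
    """Noise-free spectrum for one concentration vector (linear mixing).

    ``concentrations`` maps analyte name -> % w/w (dict or pandas Series).
    The model is linear: spectrum = background + sum_a conc_a * pure_a.
    """
    pure = pure_spectra(config)
    spec = np.zeros(config.wavelengths.size)
    for name in config.analytes:
        spec += float(concentrations[name]) * pure[name].to_numpy()
    if include_background:
        spec += background_spectrum(config)
    return spec


def distort_and_replicate(
    clean: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Produce n_replicates distorted scans of one clean spectrum.

    Each scan is b * clean + a + eps with a multiplicative scatter factor
    b = exp(N(0, scatter_log_sd)), a channel-constant baseline offset
    a ~ N(0, baseline_offset_sd), and white noise eps ~ N(0, noise_sd) per
    channel.  Returns (scans, offsets, scatter_factors) so ground-truth
    distortions can be logged.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    R = config.n_replicates
    offsets = rng.normal(0.0, config.baseline_offset_sd, size=R)
    scatter = np.exp(rng.normal(0.0, config.scatter_log_sd, size=R))
    noise = rng.normal(0.0, config.noise_sd, size=(R, clean.size))
    scans = scatter[:, None] * clean[None, :] + offsets[:, None] + noise
    return scans, offsets, scatter


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full dataset: concentrations, reference table, replicate
    scans with logged distortions.  Deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    totals = sample_concentrations(config, rng)

    # Reference table: split each total into acidic/neutral forms so the
    # decarboxylation-corrected totals reproduce the drawn values exactly.
    ref_cols = {}
    for total_name, (neutral, acidic) in ANALYTE_PAIRS.items():
        T = totals[total_name].to_numpy()
        ref_cols[neutral] = (1.0 - ACIDIC_FRACTION_OF_TOTAL) * T
        ref_cols[acidic] = ACIDIC_FRACTION_OF_TOTAL * T / DECARBOXYLATION_FACTOR
    reference = ReferenceTable(pd.DataFrame(ref_cols, index=totals.index))

    pure = pure_spectra(config)
    bg = background_spectrum(config)
    mix = totals.to_numpy() @ pure.to_numpy().T + bg  # K x I clean spectra

    scans = np.empty((config.n_samples, config.n_replicates, config.wavelengths.size))
    log_rows = []
    for k, sid in enumerate(totals.index):
        scans[k], offs, scat = distort_and_replicate(mix[k], config, rng)
        for r in range(config.n_replicates):
            log_rows.append((sid, r, offs[r], scat[r]))
    spectra = SpectraSet(config.wavelengths, list(totals.index), scans)
    log = pd.DataFrame(
        log_rows, columns=["sample_id", "replicate", "offset", "scatter"]
    )
    return SyntheticDataset(
        config=config,
        spectra=spectra,
        reference=reference,
        true_pure_spectra=pure,
        background=bg,
        distortion_log=log,
    )
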
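"""Core containers for NIR calibration data and the cannabinoid reference table.

A :class:`SpectraSet` holds a sample-by-wavelength matrix of reflectance or
absorbance values, optionally with a replicate-scan axis (sample x replicate x
wavelength).  A :class:`ReferenceTable` holds per-sample neutral and acidic
cannabinoid concentrations in % w/w of dry mass together with the derived
decarboxylation-corrected totals.  Both round-trip through plain CSV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Mass-conversion factor applied to acidic cannabinoids: on heating, the
#: carboxyl group is lost as CO2, so 1 g of e.g. CBDA yields 0.877 g of CBD.
DECARBOXYLATION_FACTOR = 0.877

#: Neutral/acidic column pairs and the total column each pair produces.
ANALYTE_PAIRS = {
    "total_CBD": ("CBD", "CBDA"),
    "total_THC": ("THC", "THCA"),
    "total_CBG": ("CBG", "CBGA"),
}

ANALYTES = tuple(ANALYTE_PAIRS)


class SpectraFormatError(ValueError):
    """Raised when an on-disk spectra file violates the expected layout."""


@dataclass
class SpectraSet:
    """A wavelength grid plus per-sample spectra.

    Parameters
    ----------
    wavelengths : ndarray, shape (I,)
        Strictly increasing grid in nm.
    samples : list of str
        Unique sample identifiers, length K.
    values : ndarray, shape (K, I) or (K, R, I)
        Spectral values; a 3-d array retains R replicate scans per sample.
    """

    wavelengths: np.ndarray
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.samples = [str(s) for s in self.samples]
        if self.wavelengths.ndim != 1 or self.wavelengths.size < 2:
            raise ValueError("wavelength grid must be 1-d with at least 2 points")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.values.ndim not in (2, 3):
            raise ValueError("values must be a (K, I) or (K, R, I) array")
        if self.values.shape[0] != len(self.samples):
            raise ValueError(
                f"{self.values.shape[0]} spectra for {len(self.samples)} sample IDs"
            )
        if self.values.shape[-1] != self.wavelengths.size:
            raise ValueError(
                f"spectra have {self.values.shape[-1]} channels, "
                f"grid has {self.wavelengths.size}"
            )
        if len(set(self.samples)) != len(self.samples):
            dup = sorted({s for s in self.samples if self.samples.count(s) > 1})
            raise ValueError(f"duplicated sample IDs: {dup}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectra contain non-finite values")
        if len(self.samples) < 1:
            raise ValueError("need at least one sample")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_channels(self) -> int:
        return int(self.wavelengths.size)

    @property
    def has_replicates(self) -> bool:
        return self.values.ndim == 3

    @property
    def n_replicates(self) -> int:
        return int(self.values.shape[1]) if self.has_replicates else 1

    def copy(self) -> "SpectraSet":
        return SpectraSet(
            self.wavelengths.copy(), list(self.samples), self.values.copy()
        )

    def with_values(self, values: np.ndarray) -> "SpectraSet":
        """Return a new set sharing this grid and sample list."""
        return SpectraSet(self.wavelengths.copy(), list(self.samples), values)


def average_replicates(spectra: SpectraSet, *, strict: bool = True) -> SpectraSet:
    """Collapse the replicate axis by a channel-wise arithmetic mean.

    Mirrors the acquisition convention of scanning each inflorescence ten
    times and modelling the average scan.  A 2-d input (already averaged,
    R = 1 conceptually) is returned as a copy, making the operation
    idempotent.

    The ``strict`` flag is part of the contract: replicate counts are equal
    by construction here (rectangular array), so it only gates future ragged
    layouts.
    """
    if not spectra.has_replicates:
        return spectra.copy()
    if spectra.values.shape[1] < 1:
        raise ValueError("need at least one replicate scan per sample")
    mean = spectra.values.mean(axis=1)
    return SpectraSet(spectra.wavelengths.copy(), list(spectra.samples), mean)


# ---------------------------------------------------------------------------
# CSV I/O
#
# Wide dialect: header "sample_id,950.0,954.0,...", one row per sample.
# Replicate dialect: header "sample_id,replicate,950.0,...", one row per scan.
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.12g"  # 12 significant digits: lossless for our value ranges


def write_spectra(spectra: SpectraSet, path) -> None:
    """Write a SpectraSet as CSV (wide or replicate dialect as appropriate)."""
    cols = [_FLOAT_FMT % w for w in spectra.wavelengths]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if spectra.has_replicates:
            fh.write("sample_id,replicate," + ",".join(cols) + "\n")
            for k, sid in enumerate(spectra.samples):
                for r in range(spectra.n_replicates):
                    row = ",".join(_FLOAT_FMT % v for v in spectra.values[k, r])
                    fh.write(f"{sid},{r},{row}\n")
        else:
            fh.write("sample_id," + ",".join(cols) + "\n")
            for k, sid in enumerate(spectra.samples):
                row = ",".join(_FLOAT_FMT % v for v in spectra.values[k])
                fh.write(f"{sid},{row}\n")


def read_spectra(path) -> SpectraSet:
    """Read a SpectraSet from CSV, accepting either dialect.

    Malformed input (ragged rows, non-numeric cells, non-increasing
    wavelength header, duplicate sample IDs) raises
    :class:`SpectraFormatError` naming the offending location.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(",")
        if not header or header[0] != "sample_id":
            raise SpectraFormatError("header must start with 'sample_id'")
        has_reps = len(header) > 1 and header[1] == "replicate"
        wl_cols = header[2:] if has_reps else header[1:]
        try:
            wavelengths = np.array([float(c) for c in wl_cols])
        except ValueError as exc:
            raise SpectraFormatError(f"non-numeric wavelength header: {exc}") from exc
        if wavelengths.size < 2 or np.any(np.diff(wavelengths) <= 0):
            raise SpectraFormatError("wavelength header must be strictly increasing")

        meta_n = 2 if has_reps else 1
        rows: list[tuple] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != meta_n + wavelengths.size:
                raise SpectraFormatError(
                    f"row {lineno}: expected {meta_n + wavelengths.size} fields, "
                    f"got {len(parts)}"
                )
            try:
                vals = np.array([float(p) for p in parts[meta_n:]])
            except ValueError:
                raise SpectraFormatError(f"row {lineno}: non-numeric value") from None
            rows.append((parts[0], int(parts[1]) if has_reps else 0, vals))

    if not rows:
        raise SpectraFormatError("no data rows")

    if has_reps:
        order: list[str] = []
        per_sample: dict[str, list[np.ndarray]] = {}
        for sid, _rep, vals in rows:
            if sid not in per_sample:
                per_sample[sid] = []
                order.append(sid)
            per_sample[sid].append(vals)
        counts = {len(v) for v in per_sample.values()}
        if len(counts) != 1:
            raise SpectraFormatError(
                f"unequal replicate counts across samples: {sorted(counts)}"
            )
        values = np.array([per_sample[sid] for sid in order])
        return SpectraSet(wavelengths, order, values)

    ids = [sid for sid, _r, _v in rows]
    if len(set(ids)) != len(ids):
        dup = sorted({s for s in ids if ids.count(s) > 1})
        raise SpectraFormatError(f"duplicated sample IDs: {dup}")
    values = np.array([vals for _s, _r, vals in rows])
    return SpectraSet(wavelengths, ids, values)


# ---------------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------------


def total_cannabinoid(neutral: float, acidic: float) -> float:
    """Total cannabinoid concentration from neutral and acidic forms, % w/w.

    total = neutral + 0.877 * acidic

    The factor 0.877 corrects the acidic form's mass for the CO2 lost on
    decarboxylation.  Applied identically for CBD/CBDA, d9-THC/THCA and
    CBG/CBGA.
    """
    neutral = np.asarray(neutral, dtype=float)
    acidic = np.asarray(acidic, dtype=float)
    if np.any(neutral < 0) or np.any(acidic < 0):
        raise ValueError("concentrations must be non-negative")
    out = neutral + DECARBOXYLATION_FACTOR * acidic
    return float(out) if out.ndim == 0 else out


@dataclass
class ReferenceTable:
    """Per-sample cannabinoid reference concentrations (% w/w dry mass).

    Wraps a DataFrame indexed by sample ID with the six measured columns
    (CBD, CBDA, THC, THCA, CBG, CBGA) and the three derived totals.  Totals
    are recomputed from the measured columns on construction so the derived
    values can never drift out of sync.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        needed = [c for pair in ANALYTE_PAIRS.values() for c in pair]
        missing = [c for c in needed if c not in self.data.columns]
        if missing:
            raise ValueError(f"reference table missing columns: {missing}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicated sample IDs in reference table")
        if (self.data[needed] < 0).any().any():
            raise ValueError("negative concentration in reference table")
        df = self.data.copy()
        df.index = df.index.astype(str)
        for total, (neutral, acidic) in ANALYTE_PAIRS.items():
            df[total] = total_cannabinoid(
                df[neutral].to_numpy(), df[acidic].to_numpy()
            )
        df["total_cannabinoids"] = sum(df[t] for t in ANALYTE_PAIRS)
        self.data = df

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def column(self, analyte: str) -> np.ndarray:
        if analyte not in self.data.columns:
            raise KeyError(f"unknown analyte column {analyte!r}")
        return self.data[analyte].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="sample_id", float_format=_FLOAT_FMT)

    @classmethod
    def from_csv(cls, path) -> "ReferenceTable":
        df = pd.read_csv(path, index_col="sample_id")
        df.index = df.index.astype(str)
        keep = [c for pair in ANALYTE_PAIRS.values() for c in pair]
        return cls(df[keep])


@dataclass(frozen=True)
class AnalyteSummary:
    """Table-1-style summary (n, min, max, mean, sample SD) of one column."""

    analyte: str
    n: int
    minimum: float
    maximum: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not (self.minimum <= self.mean <= self.maximum):
            raise ValueError("summary violates min <= mean <= max")
        if self.sd < 0:
            raise ValueError("SD must be non-negative")


def summarize_reference(table: ReferenceTable, analyte: str) -> AnalyteSummary:
    """Summarize one reference column with the n-1 SD convention."""
    col = table.column(analyte)
    if col.size == 0:
        raise ValueError("empty reference column")
    sd = float(np.std(col, ddof=1)) if col.size > 1 else 0.0
    return AnalyteSummary(
        analyte=analyte,
        n=int(col.size),
        minimum=float(col.min()),
        maximum=float(col.max()),
        mean=float(col.mean()),
        sd=sd,
    )
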
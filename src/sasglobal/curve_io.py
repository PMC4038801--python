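"""Reading and writing SAS curves and parameter files.

Experimental curves are whitespace-separated ASCII with 2, 3 or 4
columns: q [1/Angstrom], I(q), optionally sigma(q) and optionally a
per-point Gaussian resolution width.  When sigma is absent it is
generated with the power law sigma(q) = k * I(q)**alpha.

Parameter files (``gen<code>.par``) hold one optimized parameter per
row: ordinal, name, value, standard deviation, lower and upper bound.
They support the two-pass workflow in which a first run only emits the
file (f-coefficient bounds defaulting to [0, 1]) for the user to edit.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import CurveFormatError, DataError, MissingSigmaError, ParFileError


@dataclass
class ResolutionSpec:
    """Instrumental resolution attached to a curve.

    sigma_points: per-point Gaussian width of the q-resolution function
    [1/Angstrom], aligned with the curve's q grid (root-sum-square of
    wavelength-spread, collimation and detector contributions if built
    from components).  slit_length: half-length of a slit-height
    weighting function [1/Angstrom]; 0 means no slit smearing.
    """

    sigma_points: np.ndarray | None = None
    sigma_constant: float = 0.0
    slit_length: float = 0.0

    def sigma_at(self, q: np.ndarray) -> np.ndarray:
        if self.sigma_points is not None:
            return np.asarray(self.sigma_points, dtype=float)
        return np.full_like(np.asarray(q, dtype=float), float(self.sigma_constant))

    @property
    def is_trivial(self) -> bool:
        if self.slit_length > 0:
            return False
        if self.sigma_points is not None:
            return not np.any(np.asarray(self.sigma_points) > 0)
        return self.sigma_constant <= 0

    @classmethod
    def from_components(cls, q, wavelength_spread=0.0, collimation=0.0,
                        detector=0.0, slit_length=0.0):
        """Combine Gaussian width components in quadrature.

        wavelength_spread is relative (dlambda/lambda) and contributes
        q * dlambda/lambda; collimation and detector widths are already
        in q units [1/Angstrom].
        """
        q = np.asarray(q, dtype=float)
        sig = np.sqrt((q * wavelength_spread) ** 2 + collimation ** 2 + detector ** 2)
        return cls(sigma_points=sig, slit_length=slit_length)


@dataclass
class SASCurve:
    """One experimental or simulated SAS curve.

    q is strictly increasing and positive; sigma strictly positive.
    p_coeffs are the per-curve condition coefficients (temp [K],
    conc [g/l], urea [M], ...) available to link functions.
    """

    q: np.ndarray
    i_exp: np.ndarray
    sigma: np.ndarray
    units: str = "absolute"          # "absolute" (1/cm) or "arbitrary"
    p_coeffs: dict = field(default_factory=dict)
    resolution: ResolutionSpec | None = None
    label: str = ""
    flagged: np.ndarray | None = None   # points with generated sigma from |I|

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.i_exp = np.asarray(self.i_exp, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        n = self.q.size
        if n < 2 or self.i_exp.size != n or self.sigma.size != n:
            raise DataError("curve arrays must have equal length >= 2")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise DataError("q must be strictly increasing and positive")
        if np.any(self.sigma <= 0):
            raise DataError("sigma must be strictly positive")
        if self.units not in ("absolute", "arbitrary"):
            raise DataError(f"unknown units {self.units!r}")

    @property
    def n_points(self) -> int:
        return self.q.size

    def rescaled(self, factor: float) -> "SASCurve":
        """Return a copy with I and sigma multiplied by ``factor``."""
        return SASCurve(self.q.copy(), self.i_exp * factor, self.sigma * factor,
                        units=self.units, p_coeffs=dict(self.p_coeffs),
                        resolution=self.resolution, label=self.label,
                        flagged=self.flagged)


def read_curve(path, k=None, alpha=None, units="absolute", p_coeffs=None,
               label=None, slit_length=0.0) -> SASCurve:
    """Read a 2-, 3- or 4-column ASCII curve file.

    Two-column files require ``k`` (and ``alpha``) to generate
    sigma(q) = k * I(q)**alpha.  A fourth column is read as a per-point
    Gaussian resolution width.  Comment lines starting with '#' and
    blank lines are skipped; rows that fail to parse or have q <= 0 are
    rejected with a warning reporting their line numbers.
    """
    path = Path(path)
    rows, bad_lines = [], []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split()
            try:
                values = [float(v.replace("D", "E").replace("d", "e"))
                          for v in fields]
            except ValueError:
                bad_lines.append(lineno)
                continue
            if len(values) < 2:
                raise CurveFormatError(
                    f"{path}:{lineno}: fewer than 2 numeric columns")
            if ncols is None:
                ncols = len(values)
            if values[0] <= 0:
                bad_lines.append(lineno)
                continue
            rows.append(values[:ncols])
    if bad_lines:
        warnings.warn(f"{path}: rejected lines {bad_lines}", stacklevel=2)
    if not rows:
        raise CurveFormatError(f"{path}: no valid data rows")
    data = np.array(rows, dtype=float)
    q, i_exp = data[:, 0], data[:, 1]

    flagged = None
    if ncols == 2:
        if k is None:
            raise MissingSigmaError(
                f"{path}: 2-column file but no sigma power-law k given")
        if alpha is None:
            alpha = 0.5
        if k < 0:
            raise DataError("k must be >= 0")
        flagged = i_exp <= 0
        if np.any(flagged):
            warnings.warn(f"{path}: sigma generated from |I| at "
                          f"{int(flagged.sum())} non-positive points",
                          stacklevel=2)
        sigma = k * np.abs(i_exp) ** alpha
    else:
        sigma = data[:, 2]
        if np.any(sigma <= 0):
            raise DataError(f"{path}: non-positive sigma in 3-column file")

    resolution = None
    if ncols is not None and ncols >= 4:
        resolution = ResolutionSpec(sigma_points=data[:, 3],
                                    slit_length=slit_length)
    elif slit_length > 0:
        resolution = ResolutionSpec(slit_length=slit_length)

    order = np.argsort(q)
    q, i_exp, sigma = q[order], i_exp[order], sigma[order]
    if flagged is not None:
        flagged = flagged[order]
    if resolution is not None and resolution.sigma_points is not None:
        resolution.sigma_points = resolution.sigma_points[order]
    keep = np.concatenate([[True], np.diff(q) > 0])
    if not np.all(keep):
        warnings.warn(f"{path}: dropped {int((~keep).sum())} duplicate q points",
                      stacklevel=2)
        q, i_exp, sigma = q[keep], i_exp[keep], sigma[keep]
        if flagged is not None:
            flagged = flagged[keep]
        if resolution is not None and resolution.sigma_points is not None:
            resolution.sigma_points = resolution.sigma_points[keep]

    return SASCurve(q, i_exp, sigma, units=units,
                    p_coeffs=dict(p_coeffs or {}), resolution=resolution,
                    label=label if label is not None else path.stem,
                    flagged=flagged)


def write_curve(curve: SASCurve, path) -> Path:
    """Write a curve as a 3-column (q, I, sigma) ASCII file."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {curve.label}  units={curve.units}\n")
        for qi, ii, si in zip(curve.q, curve.i_exp, curve.sigma):
            fh.write(f"{qi:.6E} {ii:.6E} {si:.6E}\n")
    return path


# ---------------------------------------------------------------------------
# parameter file (gen<code>.par)
# ---------------------------------------------------------------------------

_CODE_RE = re.compile(r"^[A-Za-z0-9]{4}$")


@dataclass
class ParFileRecord:
    """One row of a gen<code>.par file."""

    ordinal: int
    name: str
    value: float
    stddev: float = 0.0
    lower: float = 0.0
    upper: float = 1.0

    def __post_init__(self):
        if self.ordinal < 1:
            raise ParFileError(f"ordinal must be >= 1, got {self.ordinal}")
        if self.stddev < 0:
            raise ParFileError("stddev must be >= 0")
        if not (self.lower <= self.value <= self.upper):
            raise ParFileError(
                f"parameter {self.name!r}: value {self.value} outside "
                f"[{self.lower}, {self.upper}]")


def _check_records(records):
    ordinals = [r.ordinal for r in records]
    if ordinals != list(range(1, len(records) + 1)):
        raise ParFileError("ordinals must be unique and contiguous from 1")


def par_file_name(code: str) -> str:
    if not _CODE_RE.match(code):
        raise ParFileError(f"run code must be 4 alphanumeric characters, "
                           f"got {code!r}")
    return f"gen{code}.par"


def write_par_file(records, code, directory=".") -> Path:
    """Write records to gen<code>.par; six whitespace-separated fields/row."""
    _check_records(records)
    path = Path(directory) / par_file_name(code)
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.ordinal} {r.name} {r.value:.6E} {r.stddev:.6E} "
                     f"{r.lower:.6E} {r.upper:.6E}\n")
    return path


def read_par_file(path):
    """Read a gen<code>.par file back into records."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            fields = stripped.split()
            if len(fields) != 6:
                raise ParFileError(f"{path}:{lineno}: expected 6 fields, "
                                   f"got {len(fields)}")
            try:
                rec = ParFileRecord(int(fields[0]), fields[1],
                                    *(float(v) for v in fields[2:]))
            except ValueError as exc:
                raise ParFileError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    _check_records(records)
    return records
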
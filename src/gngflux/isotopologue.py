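"""Mass-isotopologue distributions and isotope-correction primitives.

A metabolite measured by high-resolution LC-MS after a :sup:`13`C tracer
experiment yields a vector of intensities at nominal mass shifts m+0 ... m+n
(n = number of carbons).  Two instrumental/chemical effects separate that
measured vector from the biologically interesting distribution of *tracer*
carbons per molecule:

* natural :sup:`13`C abundance (~1.07%) in every carbon that did not come
  from the tracer, which pushes intensity upward in mass, and
* isotopic impurity of the tracer (nominal :sup:`13`C positions that are in
  fact :sup:`12`C), which pushes intensity downward.

Both effects are binomial in the number of affected carbons, so the measured
distribution is a known linear transform of the true one.  This module builds
that transform (:func:`build_correction_matrix`), inverts it by nonnegative
least squares (:func:`correct_mid`), and provides the two enrichment
summaries used throughout the package.

Correction is carbon-only: nitrogen/hydrogen/oxygen isotopes are resolved
away at the high mass resolution these experiments are acquired at, and the
tracers are carbon tracers.  The assumption is recorded in
:class:`CorrectionSettings` so an extended elemental correction could be
added without changing call sites.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "MID",
    "RawIonCounts",
    "CorrectionSettings",
    "build_correction_matrix",
    "forward_convolve",
    "correct_mid",
    "average_enrichment",
    "labeled_fraction",
]

#: Terrestrial natural abundance of 13C (fraction of all carbon).
C13_NATURAL_ABUNDANCE = 0.0107

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class MID:
    """A mass-isotopologue distribution: fractions of species m+0 ... m+n.

    Parameters
    ----------
    metabolite_name:
        Free-form label ("glucose", "GAP", ...). Never interpreted.
    fractions:
        Sequence of length ``n_carbons + 1``; entry ``i`` is the fraction of
        molecules carrying ``i`` heavy carbons.  Must be nonnegative and sum
        to 1 within ``1e-9`` unless ``normalize=True``.
    """

    metabolite_name: str
    fractions: tuple[float, ...]
    normalize: dataclasses.InitVar[bool] = False

    def __post_init__(self, normalize: bool) -> None:
        arr = np.asarray(self.fractions, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("MID needs a 1-D fraction vector for >= 1 carbon")
        if not np.all(np.isfinite(arr)):
            raise ValueError("MID fractions must be finite")
        if np.any(arr < -_SUM_TOL):
            raise ValueError(f"negative isotopologue fraction in {self.metabolite_name!r}")
        arr = np.clip(arr, 0.0, None)
        total = arr.sum()
        if normalize:
            if total <= 0:
                raise ValueError("cannot normalize an all-zero MID")
            arr = arr / total
        elif abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"MID fractions for {self.metabolite_name!r} sum to {total:.6g}, not 1"
            )
        else:
            arr = arr / total  # snap to exact unit sum
        if np.any(arr > 1.0 + _SUM_TOL):
            raise ValueError("isotopologue fraction above 1")
        object.__setattr__(self, "fractions", tuple(float(x) for x in arr))

    @property
    def n_carbons(self) -> int:
        return len(self.fractions) - 1

    def as_array(self) -> np.ndarray:
        return np.asarray(self.fractions, dtype=float)


@dataclass(frozen=True)
class RawIonCounts:
    """Uncorrected MS intensities per nominal mass shift m+0 ... m+n."""

    metabolite_name: str
    counts: tuple[float, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("ion counts need one entry per mass shift, >= 2 entries")
        if not np.all(np.isfinite(arr)):
            raise ValueError("ion counts must be finite")
        if np.any(arr < 0):
            raise ValueError(f"negative ion count for {self.metabolite_name!r}")
        if not np.any(arr > 0):
            raise ValueError(f"all-zero ion counts for {self.metabolite_name!r}")
        object.__setattr__(self, "counts", tuple(float(x) for x in arr))

    @property
    def n_carbons(self) -> int:
        return len(self.counts) - 1

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass(frozen=True)
class CorrectionSettings:
    """Parameters of the carbon-only isotope correction.

    ``c13_natural_abundance`` is the per-carbon probability that an untraced
    carbon is 13C; ``tracer_purity`` the probability that a nominal tracer
    carbon really is 13C (vendor lots are typically 99%).
    """

    c13_natural_abundance: float = C13_NATURAL_ABUNDANCE
    tracer_purity: float = 0.99
    resolution_assumption: str = "carbon-only"

    def __post_init__(self) -> None:
        if not (0.0 < self.c13_natural_abundance < 1.0):
            raise ValueError("c13_natural_abundance must lie in (0, 1)")
        if not (0.0 < self.tracer_purity <= 1.0):
            raise ValueError("tracer_purity must lie in (0, 1]")
        if self.resolution_assumption != "carbon-only":
            raise ValueError("only carbon-only correction is implemented")


def build_correction_matrix(
    n_carbons: int, settings: CorrectionSettings | None = None
) -> np.ndarray:
    """Expected measured distribution per true tracer-carbon count.

    Column ``j`` of the returned ``(n+1) x (n+1)`` matrix is the measured
    mass-shift distribution of a molecule carrying exactly ``j`` tracer
    carbons: a Binomial(j, purity) number of the tracer carbons are heavy,
    plus a Binomial(n-j, natural abundance) contribution from the remaining
    carbons.  Columns are probability vectors (they sum to 1; no shift can
    exceed m+n for a carbon-only model).
    """
    if n_carbons < 1:
        raise ValueError("n_carbons must be >= 1")
    settings = settings or CorrectionSettings()
    a = settings.c13_natural_abundance
    p = settings.tracer_purity
    n = n_carbons
    mat = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        natural = stats.binom.pmf(np.arange(n - j + 1), n - j, a)
        tracer = stats.binom.pmf(np.arange(j + 1), j, p)
        mat[:, j] = np.convolve(tracer, natural)[: n + 1]
    return mat


def forward_convolve(mid: MID, settings: CorrectionSettings | None = None) -> np.ndarray:
    """Expected measured fraction vector for a true tracer-carbon MID."""
    mat = build_correction_matrix(mid.n_carbons, settings)
    return mat @ mid.as_array()


def correct_mid(raw: RawIonCounts, settings: CorrectionSettings | None = None) -> MID:
    """Recover the tracer-carbon MID from raw intensities.

    Solves ``min ||M x - counts||`` subject to ``x >= 0`` and renormalizes,
    so noisy inputs can never produce negative fractions.  On counts produced
    by noise-free forward convolution the original MID is recovered exactly
    (the matrix is triangular-dominant and full rank).
    """
    counts = raw.as_array()
    mat = build_correction_matrix(raw.n_carbons, settings)
    solution, _ = optimize.nnls(mat, counts)
    if solution.sum() <= 0:
        raise ValueError(f"correction produced an all-zero MID for {raw.metabolite_name!r}")
    return MID(raw.metabolite_name, tuple(solution), normalize=True)


def average_enrichment(mid: MID) -> float:
    """Fraction of the molecule's carbons that are heavy: sum(i * f_i) / n."""
    arr = mid.as_array()
    return float(np.dot(np.arange(arr.size), arr) / mid.n_carbons)


def labeled_fraction(mid: MID) -> float:
    """Fraction of molecules carrying at least one heavy carbon: 1 - f_0."""
    return 1.0 - mid.fractions[0]
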
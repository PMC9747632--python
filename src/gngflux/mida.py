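"""Mass isotopomer distribution analysis for the triose->hexose dimer.

Gluconeogenic glucose is assembled from two triose phosphates (GAP + DHAP,
assumed in rapid equilibrium and therefore isotopically exchangeable).  If
the triose ("monomer") pool has isotopologue distribution ``m``, and the two
halves of each glucose are drawn independently from that pool, the glucose
("dimer") distribution is the self-convolution of ``m`` — the binomial / MIDA
relationship.  Under a single labeled monomer species (m+1 for a 2-13C
tracer, m+3 for U-13C) the dimer carries a characteristic pair of peaks
whose ratio ``2(1-p)/p`` depends only on the monomer labeled fraction ``p``,
so a *dilution* of the monomer pool by unlabeled carbon is read directly off
the glucose spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .isotopologue import MID, labeled_fraction

__all__ = [
    "MonomerPool",
    "DimerPrediction",
    "monomer_mid_from_fraction",
    "predict_dimer",
    "infer_monomer_fraction",
    "dilution_ratio",
]

#: labeling schemes: which monomer isotopologue the tracer produces
SCHEMES = {"U13C": 3, "2-13C": 1}

_RATIO_EPS = 1e-12


@dataclass(frozen=True)
class MonomerPool:
    """Triose-phosphate (GAP/DHAP) monomer pool with its labeled fraction."""

    monomer_mid: MID

    def __post_init__(self) -> None:
        if self.monomer_mid.n_carbons != 3:
            raise ValueError("monomer pool must be a 3-carbon MID")

    @property
    def p(self) -> float:
        return labeled_fraction(self.monomer_mid)


@dataclass(frozen=True)
class DimerPrediction:
    """Predicted hexose MID plus the two scheme-diagnostic peak ratios.

    Ratios are ``None`` when their denominator is numerically zero.
    """

    hexose_mid: MID
    ratio_m1_m2: float | None
    ratio_m3_m6: float | None


def monomer_mid_from_fraction(p: float, scheme: str, name: str = "triose") -> MID:
    """Single-species monomer MID: fraction ``p`` at the scheme's mass shift."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {sorted(SCHEMES)}")
    if not (0.0 <= p <= 1.0):
        raise ValueError("labeled fraction must lie in [0, 1]")
    fractions = [0.0] * 4
    fractions[0] = 1.0 - p
    fractions[SCHEMES[scheme]] = p
    return MID(name, tuple(fractions))


def predict_dimer(monomer: MonomerPool | MID) -> DimerPrediction:
    """Hexose MID from two i.i.d. draws out of the monomer pool.

    fraction of hexose m+k = sum_{i+j=k} mono_i * mono_j (self-convolution).
    """
    mid = monomer.monomer_mid if isinstance(monomer, MonomerPool) else monomer
    if mid.n_carbons != 3:
        raise ValueError("dimer prediction needs a 3-carbon monomer MID")
    mono = mid.as_array()
    hexose = np.convolve(mono, mono)
    hex_mid = MID("glucose", tuple(hexose), normalize=True)

    def _ratio(num: float, den: float) -> float | None:
        return None if den < _RATIO_EPS else float(num / den)

    return DimerPrediction(
        hexose_mid=hex_mid,
        ratio_m1_m2=_ratio(hexose[1], hexose[2]),
        ratio_m3_m6=_ratio(hexose[3], hexose[6]),
    )


def infer_monomer_fraction(hexose: MID, scheme: str) -> float:
    """Monomer labeled fraction that best explains an observed hexose MID.

    Bounded scalar least squares over ``p`` in [0, 1]; round-trips
    :func:`predict_dimer` to 1e-6 on noise-free input.  An all-m+0 hexose
    returns 0.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {sorted(SCHEMES)}")
    if hexose.n_carbons != 6:
        raise ValueError("hexose MID must have 6 carbons")
    observed = hexose.as_array()
    if observed[0] >= 1.0 - _RATIO_EPS:
        return 0.0

    def loss(p: float) -> float:
        predicted = predict_dimer(monomer_mid_from_fraction(p, scheme)).hexose_mid
        return float(np.sum((predicted.as_array() - observed) ** 2))

    result = optimize.minimize_scalar(
        loss, bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-10}
    )
    return float(result.x)


def dilution_ratio(monomer_p: float) -> float:
    """Singly/doubly labeled dimer ratio ``2(1-p)/p`` at monomer fraction p.

    This is m+1/m+2 under a 2-13C tracer and m+3/m+6 under U-13C; it rises
    when unlabeled carbon dilutes the monomer pool, which is how a shift in
    triose-pool sourcing shows up in the glucose spectrum.
    """
    if not (0.0 < monomer_p <= 1.0):
        raise ValueError("dilution ratio undefined: labeled fraction must be in (0, 1]")
    return 2.0 * (1.0 - monomer_p) / monomer_p
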
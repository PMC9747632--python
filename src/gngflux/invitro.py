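"""Steady-state attribution of gluconeogenic carbon in hepatocyte cultures.

Three parallel incubations carry the same four-substrate mix (glutamine,
glycerol, pyruvate, lactate at fasting serum concentrations) with a
different substrate 13C-labeled in each — glycerol (Gro), pyruvate/lactate
(PL, one pool), or glutamine (Gln).  Because concentrations are identical
across schemes, the labeled fraction each scheme produces in the
triose-phosphate pool measures that substrate's fractional contribution to
triose carbon, and hence to glucose.  The triose pool is treated as the
single mixing node; carbon lost as CO2 while a TCA-transiting substrate
(PL, Gln) travels to the triose pool is summarized by a scalar loss factor
per substrate, estimated from within-molecule label dilution.

Flux attribution is then a one-liner: total carbon flux into glucose is
6 x the glucose production rate, and substrate x receives the share f_x of
it.  :func:`summarize_condition_pair` reproduces the ratio / percentage /
fold-change bookkeeping used to compare basal and glucagon-stimulated
conditions, with ratios rounded to one decimal and percentages to integers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .isotopologue import MID, RawIonCounts, average_enrichment, labeled_fraction
from .mida import infer_monomer_fraction

__all__ = [
    "SCHEME_IDS",
    "SchemeResult",
    "TrioseMix",
    "FluxEstimate",
    "ConditionComparison",
    "triose_mix_from_schemes",
    "tca_loss_factor",
    "estimate_fluxes",
    "summarize_condition_pair",
    "m3_m6_ratio",
]

SCHEME_IDS = ("Gro-labeled", "PL-labeled", "Gln-labeled")
SUBSTRATES = ("gro", "pl", "gln")
_SCHEME_TO_SUBSTRATE = dict(zip(SCHEME_IDS, SUBSTRATES))

#: above this excess over 1, three scheme fractions are deemed inconsistent
OVERSUM_TOLERANCE = 0.05

#: carbons per glucose molecule
GLUCOSE_CARBONS = 6


@dataclass(frozen=True)
class SchemeResult:
    """Measurements from one labeling scheme of one condition.

    ``triose_mid`` is the directly measured GAP (or GAP+DHAP) distribution;
    when absent, the triose labeled fraction is inferred from the glucose
    MID through the dimer model.  ``tracer_scheme`` states which mass shift
    the tracer produces in the triose pool ("U13C" or "2-13C"); it matters
    only for that inference.  Optional raw ion-count vectors are carried for
    provenance when the result came from uncorrected instrument tables.
    """

    scheme_id: str
    glucose_mid: MID
    glucose_production_rate: float  # nmol glucose/h
    triose_mid: MID | None = None
    tracer_scheme: str = "U13C"
    raw_glucose_counts: RawIonCounts | None = None
    raw_triose_counts: RawIonCounts | None = None

    def __post_init__(self) -> None:
        if self.scheme_id not in SCHEME_IDS:
            raise ValueError(f"scheme_id must be one of {SCHEME_IDS}")
        if self.glucose_mid.n_carbons != GLUCOSE_CARBONS:
            raise ValueError("glucose MID must have 6 carbons")
        if self.triose_mid is not None and self.triose_mid.n_carbons != 3:
            raise ValueError("triose MID must have 3 carbons")
        if self.glucose_production_rate < 0:
            raise ValueError("glucose production rate must be >= 0")

    def triose_labeled_fraction(self) -> float:
        if self.triose_mid is not None:
            return labeled_fraction(self.triose_mid)
        return infer_monomer_fraction(self.glucose_mid, self.tracer_scheme)


@dataclass(frozen=True)
class TrioseMix:
    """Fractional composition of the triose-phosphate pool by carbon source."""

    f_gro: float
    f_pl: float
    f_gln: float
    f_unlabeled: float

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if not (-1e-12 <= value <= 1.0 + 1e-12):
                raise ValueError(f"{name} = {value} outside [0, 1]")
        if abs(sum(self.as_dict().values()) - 1.0) > 1e-9:
            raise ValueError("triose mix fractions must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return {
            "gro": self.f_gro,
            "pl": self.f_pl,
            "gln": self.f_gln,
            "unlabeled": self.f_unlabeled,
        }


@dataclass(frozen=True)
class FluxEstimate:
    """Per-substrate carbon flux (nmol C/h) into the triose/glucose pool."""

    total_flux: float
    j_gro: float
    j_pl: float
    j_gln: float
    tca_loss: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("total_flux", "j_gro", "j_pl", "j_gln"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.j_gro + self.j_pl + self.j_gln > self.total_flux * (1 + 1e-9):
            raise ValueError("substrate fluxes exceed total carbon flux")

    @property
    def labeled_total(self) -> float:
        return self.j_gro + self.j_pl + self.j_gln

    def fluxes(self) -> dict[str, float]:
        return {"gro": self.j_gro, "pl": self.j_pl, "gln": self.j_gln}

    def shares(self) -> dict[str, float]:
        """Percent contribution of each substrate among labeled carbon."""
        total = self.labeled_total
        if total <= 0:
            return {key: float("nan") for key in SUBSTRATES}
        return {key: 100.0 * value / total for key, value in self.fluxes().items()}


def triose_mix_from_schemes(results: list[SchemeResult] | tuple[SchemeResult, ...]) -> TrioseMix:
    """Combine the three one-labeled-substrate schemes into a pool mix.

    The labeled fraction of the triose pool in scheme x *is* substrate x's
    fractional contribution; the remainder is unlabeled endogenous carbon.
    A mild oversum (< 5 percentage points, measurement noise) is
    renormalized with a warning; beyond that the schemes are inconsistent
    and an error is raised.
    """
    by_substrate: dict[str, float] = {}
    for result in results:
        substrate = _SCHEME_TO_SUBSTRATE[result.scheme_id]
        if substrate in by_substrate:
            raise ValueError(f"duplicate scheme {result.scheme_id!r}")
        by_substrate[substrate] = result.triose_labeled_fraction()
    missing = set(SUBSTRATES) - set(by_substrate)
    if missing:
        raise ValueError(f"missing labeling scheme(s) for: {sorted(missing)}")

    total = sum(by_substrate.values())
    if total > 1.0 + OVERSUM_TOLERANCE:
        raise ValueError(
            f"scheme labeled fractions sum to {total:.3f} > 1 + {OVERSUM_TOLERANCE}; "
            "schemes are mutually inconsistent"
        )
    if total > 1.0:
        warnings.warn(
            f"labeled fractions oversum to {total:.4f}; renormalizing and "
            "setting the unlabeled share to 0",
            stacklevel=2,
        )
        by_substrate = {key: value / total for key, value in by_substrate.items()}
        total = 1.0
    return TrioseMix(
        f_gro=by_substrate["gro"],
        f_pl=by_substrate["pl"],
        f_gln=by_substrate["gln"],
        f_unlabeled=1.0 - total,
    )


def tca_loss_factor(mid: MID, max_label: int | None = None) -> float:
    """Carbon-loss factor from within-molecule label dilution.

    A U-13C substrate entering intact would deliver ``max_label`` heavy
    carbons per labeled product molecule (3 for a triose); passage through
    the TCA cycle sheds some as CO2, producing m+1/m+2 species.  The loss
    factor is 1 - (mean heavy carbons per *labeled* molecule) / max_label.
    """
    if max_label is None:
        max_label = mid.n_carbons
    lf = labeled_fraction(mid)
    if lf < 1e-12:
        raise ValueError("loss factor undefined for an unlabeled distribution")
    mean_label = average_enrichment(mid) * mid.n_carbons / lf
    return float(np.clip(1.0 - mean_label / max_label, 0.0, 1.0))


def estimate_fluxes(
    mix: TrioseMix,
    glucose_rate: float,
    tca_loss: dict[str, float] | None = None,
) -> FluxEstimate:
    """Apportion total gluconeogenic carbon flux by triose-pool shares.

    ``glucose_rate`` is media glucose accumulation in nmol glucose/h; total
    carbon flux is 6x that.  ``tca_loss`` carries the per-substrate loss
    factors (from :func:`tca_loss_factor`) as a separate readout — the
    attribution itself is by labeled fraction at the mixing node.
    """
    if glucose_rate <= 0:
        raise ValueError("glucose production rate must be > 0")
    total = GLUCOSE_CARBONS * glucose_rate
    return FluxEstimate(
        total_flux=total,
        j_gro=mix.f_gro * total,
        j_pl=mix.f_pl * total,
        j_gln=mix.f_gln * total,
        tca_loss=dict(tca_loss or {}),
    )


@dataclass(frozen=True)
class ConditionComparison:
    """Basal vs stimulated flux bookkeeping (raw values; rounding on demand).

    The glycerol:TCA ratio divides the glycerol flux by the summed
    pyruvate/lactate + glutamine fluxes.  Fold changes are
    stimulated / basal and are NaN when the basal flux is zero.
    """

    basal: FluxEstimate
    stimulated: FluxEstimate

    @staticmethod
    def _gro_tca_ratio(estimate: FluxEstimate) -> float:
        tca = estimate.j_pl + estimate.j_gln
        return float("nan") if tca <= 0 else estimate.j_gro / tca

    @property
    def glycerol_tca_ratio_basal(self) -> float:
        return self._gro_tca_ratio(self.basal)

    @property
    def glycerol_tca_ratio_stimulated(self) -> float:
        return self._gro_tca_ratio(self.stimulated)

    def fold_changes(self) -> dict[str, float]:
        folds = {}
        for key in SUBSTRATES:
            basal = self.basal.fluxes()[key]
            stim = self.stimulated.fluxes()[key]
            folds[key] = stim / basal if basal > 0 else float("nan")
        folds["total"] = (
            self.stimulated.total_flux / self.basal.total_flux
            if self.basal.total_flux > 0
            else float("nan")
        )
        return folds

    def rounded(self) -> dict[str, float | None]:
        """Summary with the reporting conventions: ratios and folds to one
        decimal, percentages to integers; undefined entries map to None."""

        def r1(x: float) -> float | None:
            return None if math.isnan(x) else round(x, 1)

        def pct(x: float) -> int | None:
            return None if math.isnan(x) else int(round(x))

        folds = self.fold_changes()
        out: dict[str, float | None] = {
            "glycerol_tca_ratio_basal": r1(self.glycerol_tca_ratio_basal),
            "glycerol_tca_ratio_stimulated": r1(self.glycerol_tca_ratio_stimulated),
            "total_fold_change": r1(folds["total"]),
        }
        for key in SUBSTRATES:
            out[f"{key}_share_basal_pct"] = pct(self.basal.shares()[key])
            out[f"{key}_share_stimulated_pct"] = pct(self.stimulated.shares()[key])
            out[f"{key}_fold_change"] = r1(folds[key])
        return out


def summarize_condition_pair(basal: FluxEstimate, stimulated: FluxEstimate) -> ConditionComparison:
    """Pair two flux estimates for basal-vs-stimulated comparison."""
    return ConditionComparison(basal=basal, stimulated=stimulated)


def m3_m6_ratio(glucose_mid: MID) -> float:
    """Glucose m+3/m+6 ratio after a U-13C 3-carbon tracer.

    Diagnoses how much of the triose pool was unlabeled: one labeled triose
    pairs with an unlabeled one (m+3) versus two labeled trioses (m+6).
    """
    if glucose_mid.n_carbons != 6:
        raise ValueError("m+3/m+6 ratio needs a 6-carbon MID")
    m6 = glucose_mid.fractions[6]
    if m6 <= 1e-12:
        raise ValueError("m+3/m+6 ratio undefined: no m+6 signal")
    return glucose_mid.fractions[3] / m6
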
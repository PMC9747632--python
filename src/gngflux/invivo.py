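"""Circulatory turnover and the glycerol-glucose-lactate flux network.

Steady-state tracer infusions (U-13C glycerol, pyruvate/lactate, or glucose
delivered at a constant rate into the jugular vein) dilute into the
endogenous turnover of the infused metabolite.  The classic turnover
relation

    Fcirc = infusion_rate * (1 / tracer_fraction - 1)

gives the endogenous rate of appearance of the infused species from its
steady-state enrichment.  Cross-labeling of the *other* circulating
metabolites then constrains how carbon flows between them.

The network model has three circulating nodes (glycerol, glucose, lactate)
and seven nonnegative carbon fluxes (umol C/min):

    lipolysis -> Gro          (unlabeled endogenous glycerol appearance)
    Gro -> Glc                (direct gluconeogenesis from glycerol; lossless)
    Gro -> sink               (glycerol oxidation / other fates)
    Lac -> Glc                (gluconeogenesis from lactate; transits the TCA
                               cycle, shedding the fraction ``tca_loss`` of
                               its label as CO2)
    Glc -> Lac                (glycolysis in peripheral tissue; Cori cycle)
    Glc -> sink               (glucose uptake/oxidation)
    Lac -> sink               (lactate oxidation)

There is deliberately no Lac->Gro or Glc->Gro edge: glycerol appears only
from lipolysis, matching the observation that circulating glycerol acquires
almost no label from lactate or glucose.  At steady state each node's
enrichment equals label inflow over carbon inflow,

    e_node = sum_in(flux * e_upstream * (1 - loss)) / sum_in(flux),

with the infusion entering its node at enrichment 1.  The system is linear
in the three enrichments and is solved in closed form.  Fluxes are fitted to
the observed enrichments of all three infusions simultaneously by a seeded
differential-evolution search with a local least-squares polish, subject to
node carbon balance (sinks are derived, not free) and the Fcirc constraints.
Confidence intervals come from a parametric bootstrap.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "NODES",
    "NODE_CARBONS",
    "TRACER_NODE",
    "InfusionExperiment",
    "FcircResult",
    "FluxNetwork",
    "InfusionNetworkFit",
    "compute_fcirc",
    "contribution_ratio",
    "predict_enrichments",
    "fit_network",
    "confidence_intervals",
]

NODES = ("glycerol", "glucose", "lactate")
NODE_CARBONS = {"glycerol": 3, "glucose": 6, "lactate": 3}
TRACERS = ("glycerol", "pyruvate/lactate", "glucose")
#: circulating node each tracer labels directly
TRACER_NODE = {"glycerol": "glycerol", "pyruvate/lactate": "lactate", "glucose": "glucose"}

_BALANCE_RTOL = 1e-6
_FREE_PARAMS = (
    "lipolysis_to_glycerol",
    "glycerol_to_glucose",
    "lactate_to_glucose",
    "glucose_to_lactate",
    "tca_loss",
)


@dataclass(frozen=True)
class FluxNetwork:
    """Edge carbon fluxes (umol C/min) of the 3-node circulatory network."""

    lipolysis_to_glycerol: float
    glycerol_to_glucose: float
    glycerol_to_sink: float
    lactate_to_glucose: float
    glucose_to_lactate: float
    glucose_to_sink: float
    lactate_to_sink: float
    tca_loss: float = 0.0

    EDGES = (
        "lipolysis_to_glycerol",
        "glycerol_to_glucose",
        "glycerol_to_sink",
        "lactate_to_glucose",
        "glucose_to_lactate",
        "glucose_to_sink",
        "lactate_to_sink",
    )

    def __post_init__(self) -> None:
        for name in self.EDGES:
            value = getattr(self, name)
            if value < -1e-9:
                raise ValueError(f"flux {name} must be >= 0, got {value}")
            object.__setattr__(self, name, max(0.0, float(value)))
        if not (0.0 <= self.tca_loss <= 1.0):
            raise ValueError("tca_loss must lie in [0, 1]")
        for node, inflow, outflow in self._balances():
            scale = max(1.0, inflow, outflow)
            if abs(inflow - outflow) > _BALANCE_RTOL * scale:
                raise ValueError(
                    f"carbon imbalance at {node}: in {inflow:.6g} vs out {outflow:.6g}"
                )

    def _balances(self) -> list[tuple[str, float, float]]:
        return [
            (
                "glycerol",
                self.lipolysis_to_glycerol,
                self.glycerol_to_glucose + self.glycerol_to_sink,
            ),
            (
                "glucose",
                self.glycerol_to_glucose + self.lactate_to_glucose,
                self.glucose_to_lactate + self.glucose_to_sink,
            ),
            (
                "lactate",
                self.glucose_to_lactate,
                self.lactate_to_glucose + self.lactate_to_sink,
            ),
        ]

    @classmethod
    def from_free_params(
        cls,
        lipolysis_to_glycerol: float,
        glycerol_to_glucose: float,
        lactate_to_glucose: float,
        glucose_to_lactate: float,
        tca_loss: float,
    ) -> "FluxNetwork":
        """Build a balanced network from the five free parameters.

        The three sink fluxes are fixed by carbon balance; they must come
        out nonnegative for the parameter vector to be feasible.
        """
        gro_sink = lipolysis_to_glycerol - glycerol_to_glucose
        glc_sink = glycerol_to_glucose + lactate_to_glucose - glucose_to_lactate
        lac_sink = glucose_to_lactate - lactate_to_glucose
        return cls(
            lipolysis_to_glycerol=lipolysis_to_glycerol,
            glycerol_to_glucose=glycerol_to_glucose,
            glycerol_to_sink=gro_sink,
            lactate_to_glucose=lactate_to_glucose,
            glucose_to_lactate=glucose_to_lactate,
            glucose_to_sink=glc_sink,
            lactate_to_sink=lac_sink,
            tca_loss=tca_loss,
        )

    def edge_fluxes(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.EDGES}

    def free_params(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in _FREE_PARAMS])


@dataclass(frozen=True)
class InfusionExperiment:
    """One steady-state tracer infusion in one animal (or synthetic mouse).

    ``infusion_rate`` is in tracee molecules per minute (e.g. umol/min,
    computed upstream from ul/g/min x mM x body mass); enrichments are
    average carbon enrichments per node.  Units must be consistent across
    the experiments handed to :func:`fit_network`; fitted fluxes come out
    in the matching carbon units.
    """

    tracer: str
    infusion_rate: float
    body_mass: float
    steady_state_enrichments: dict[str, float]
    steady_state_mids: dict[str, object] | None = None

    def __post_init__(self) -> None:
        if self.tracer not in TRACER_NODE:
            raise ValueError(f"tracer must be one of {TRACERS}")
        if self.infusion_rate <= 0:
            raise ValueError("infusion rate must be > 0")
        if self.body_mass <= 0:
            raise ValueError("body mass must be > 0")
        for node, value in self.steady_state_enrichments.items():
            if node not in NODES:
                raise ValueError(f"unknown node {node!r}")
            if not (0.0 <= value < 1.0):
                raise ValueError(f"enrichment of {node} must lie in [0, 1)")
        if self.steady_state_enrichments.get(self.infused_node, 0.0) <= 0.0:
            raise ValueError("the infused node must show positive enrichment")

    @property
    def infused_node(self) -> str:
        return TRACER_NODE[self.tracer]

    @property
    def carbon_infusion_rate(self) -> float:
        """Infusion rate in carbon units (tracee rate x carbons/molecule)."""
        return self.infusion_rate * NODE_CARBONS[self.infused_node]


@dataclass(frozen=True)
class FcircResult:
    """Endogenous turnover of one circulating metabolite."""

    node: str
    fcirc: float
    tracer_fraction: float


def compute_fcirc(exp: InfusionExperiment, per_gram: bool = False) -> FcircResult:
    """Endogenous turnover: Fcirc = infusion_rate * (1/fraction - 1).

    Units follow ``exp.infusion_rate``; with ``per_gram=True`` the result is
    normalized by body mass (nmol/g/min-style reporting).
    """
    fraction = exp.steady_state_enrichments[exp.infused_node]
    if not (0.0 < fraction < 1.0):
        raise ValueError("tracer fraction of the infused node must lie in (0, 1)")
    fcirc = exp.infusion_rate * (1.0 / fraction - 1.0)
    if per_gram:
        fcirc /= exp.body_mass
    return FcircResult(node=exp.infused_node, fcirc=fcirc, tracer_fraction=fraction)


def contribution_ratio(donor_enrichment: float, recipient_enrichment: float) -> float:
    """Fractional carbon contribution of a sole labeled precursor.

    When the donor is the only 13C source at steady state, the recipient's
    share of donor-derived carbon is recipient/donor enrichment.  A
    recipient above the donor (noise) is clipped to 1 with a warning.
    """
    if donor_enrichment <= 0:
        raise ValueError("donor enrichment must be > 0")
    if recipient_enrichment < 0:
        raise ValueError("recipient enrichment must be >= 0")
    if recipient_enrichment > donor_enrichment:
        warnings.warn(
            "recipient enrichment exceeds donor enrichment; clipping ratio to 1",
            stacklevel=2,
        )
        return 1.0
    return recipient_enrichment / donor_enrichment


# ---------------------------------------------------------------------------
# steady-state enrichment model


def _enrichments_from_params(
    params: np.ndarray, rates: tuple[float, float, float]
) -> tuple[float, float, float]:
    """Closed-form steady-state enrichments (e_gro, e_glc, e_lac).

    ``rates`` are the carbon infusion rates entering (glycerol, glucose,
    lactate); at most one is nonzero per experiment.  Derived by
    substituting the lactate balance into the glucose balance of the linear
    system described in the module docstring.
    """
    f_lip, f_groglc, f_lacglc, f_glclac, loss = params
    r_gro, r_glc, r_lac = rates

    denom_gro = f_lip + r_gro
    e_gro = r_gro / denom_gro if denom_gro > 0 else 0.0

    lac_in = f_glclac + r_lac
    recycle = f_glclac / lac_in if lac_in > 0 else 0.0
    lac_source = r_lac / lac_in if lac_in > 0 else 0.0

    denom_glc = f_groglc + f_lacglc + r_glc - f_lacglc * (1.0 - loss) * recycle
    num_glc = r_glc + f_groglc * e_gro + f_lacglc * (1.0 - loss) * lac_source
    e_glc = num_glc / denom_glc if denom_glc > 1e-300 else 0.0

    e_lac = (f_glclac * e_glc + r_lac) / lac_in if lac_in > 0 else 0.0
    return e_gro, e_glc, e_lac


def predict_enrichments(
    network: FluxNetwork, tracer: str, carbon_infusion_rate: float
) -> dict[str, float]:
    """Steady-state node enrichments under one tracer infusion."""
    if tracer not in TRACER_NODE:
        raise ValueError(f"tracer must be one of {TRACERS}")
    if carbon_infusion_rate <= 0:
        raise ValueError("carbon infusion rate must be > 0")
    node = TRACER_NODE[tracer]
    rates = tuple(
        carbon_infusion_rate if node == n else 0.0 for n in ("glycerol", "glucose", "lactate")
    )
    e_gro, e_glc, e_lac = _enrichments_from_params(network.free_params(), rates)
    return {"glycerol": e_gro, "glucose": e_glc, "lactate": e_lac}


# ---------------------------------------------------------------------------
# fitting


@dataclass(frozen=True)
class InfusionNetworkFit:
    """Best-fit network with the data it was fitted to and optional CIs."""

    best_fit: FluxNetwork
    objective: float
    seed: int
    experiments: tuple[InfusionExperiment, ...]
    fcircs: dict[str, FcircResult]
    ci_lower: dict[str, float] | None = None
    ci_upper: dict[str, float] | None = None
    noise_scale: float | None = None

    def estimates(self) -> dict[str, float]:
        out = self.best_fit.edge_fluxes()
        out["tca_loss"] = self.best_fit.tca_loss
        return out


def _prepare(experiments, fcircs):
    exps = tuple(sorted(experiments, key=lambda e: e.tracer))
    if len({e.tracer for e in exps}) != len(exps) or len(exps) != 3:
        raise ValueError("need exactly one experiment per tracer")
    fdict = {f.node: f for f in (fcircs.values() if isinstance(fcircs, dict) else fcircs)}
    if set(fdict) != set(NODES):
        raise ValueError(f"need one Fcirc per node {NODES}")
    return exps, fdict


def _residuals(params, exps, fdict):
    res = []
    for exp in exps:
        node = exp.infused_node
        rates = tuple(
            exp.carbon_infusion_rate if node == n else 0.0
            for n in ("glycerol", "glucose", "lactate")
        )
        pred = dict(zip(NODES, _enrichments_from_params(params, rates)))
        # enrichment noise is multiplicative, so misfit is measured on the
        # log scale; structurally-zero observations only penalize pred > 0
        for obs_node, observed in sorted(exp.steady_state_enrichments.items()):
            if observed > 1e-9:
                res.append(np.log(max(pred[obs_node], 1e-12) / observed))
            else:
                res.append(100.0 * pred[obs_node])
        # Fcirc constraint: the turnover implied by the predicted enrichment
        # of the infused node must match the measured one (relative scale).
        e_inf = pred[node]
        measured = fdict[node].fcirc * NODE_CARBONS[node]
        if e_inf <= 1e-12:
            res.append(10.0)
        else:
            implied = exp.carbon_infusion_rate * (1.0 / e_inf - 1.0)
            res.append((implied - measured) / max(measured, 1e-12))
    # feasibility: derived sink fluxes must be nonnegative
    f_lip, f_groglc, f_lacglc, f_glclac, _ = params
    scale = max(1.0, f_lip, f_groglc + f_lacglc, f_glclac)
    for sink in (
        f_lip - f_groglc,
        f_groglc + f_lacglc - f_glclac,
        f_glclac - f_lacglc,
    ):
        res.append(100.0 * max(0.0, -sink) / scale)
    return np.asarray(res)


def fit_network(
    experiments,
    fcircs,
    seed: int,
    popsize: int = 20,
    maxiter: int = 250,
) -> InfusionNetworkFit:
    """Fit the 7-edge network to three steady-state infusions.

    Global stage: seeded :func:`scipy.optimize.differential_evolution` over
    the five free parameters (four independent fluxes + TCA loss), bounded
    by ten times the largest measured carbon turnover.  Local stage:
    trust-region least squares from the global optimum.  Deterministic for
    a given seed and budget.
    """
    exps, fdict = _prepare(experiments, fcircs)
    upper = 10.0 * max(
        fdict[node].fcirc * NODE_CARBONS[node] for node in NODES
    )
    if upper <= 0:
        raise ValueError("all measured turnovers are zero; nothing to fit")
    bounds = [(0.0, upper)] * 4 + [(0.0, 1.0)]

    def objective(theta: np.ndarray) -> float:
        return float(np.sum(_residuals(theta, exps, fdict) ** 2))

    de = optimize.differential_evolution(
        objective,
        bounds=bounds,
        seed=seed,
        popsize=popsize,
        maxiter=maxiter,
        tol=1e-12,
        polish=True,
        init="latinhypercube",
    )
    lower_b = np.zeros(5)
    upper_b = np.array([upper] * 4 + [1.0])
    x0 = np.clip(de.x, lower_b + 1e-12, upper_b - 1e-12)
    polish = optimize.least_squares(
        _residuals,
        x0,
        args=(exps, fdict),
        bounds=(lower_b, upper_b),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    best = polish.x if np.sum(polish.fun**2) <= de.fun else de.x
    network = FluxNetwork.from_free_params(*_clip_feasible(best))
    fit = InfusionNetworkFit(
        best_fit=network,
        objective=float(np.sum(_residuals(best, exps, fdict) ** 2)),
        seed=seed,
        experiments=exps,
        fcircs=fdict,
    )
    if fit.objective > 1e2:
        raise RuntimeError(
            f"no feasible network found (objective {fit.objective:.3g}); "
            f"residuals: {_residuals(best, exps, fdict)}"
        )
    return fit


def _clip_feasible(params: np.ndarray) -> np.ndarray:
    """Project a near-feasible parameter vector onto the feasible set.

    The optimizer's penalty drives sink fluxes to >= -1e-9-ish; snap the
    tiny violations so the balanced network construction succeeds.
    """
    f_lip, f_groglc, f_lacglc, f_glclac, loss = np.clip(params, 0.0, None)
    loss = min(loss, 1.0)
    f_groglc = min(f_groglc, f_lip)
    f_glclac = min(f_glclac, f_groglc + f_lacglc)
    f_lacglc = min(f_lacglc, f_glclac)
    return np.array([f_lip, f_groglc, f_lacglc, f_glclac, loss])


def _estimate_noise_scale(fit: InfusionNetworkFit) -> float:
    params = fit.best_fit.free_params()
    logs = []
    for exp in fit.experiments:
        node = exp.infused_node
        rates = tuple(
            exp.carbon_infusion_rate if node == n else 0.0
            for n in ("glycerol", "glucose", "lactate")
        )
        pred = dict(zip(NODES, _enrichments_from_params(params, rates)))
        for obs_node, observed in exp.steady_state_enrichments.items():
            if observed > 1e-12 and pred[obs_node] > 1e-12:
                logs.append(np.log(observed / pred[obs_node]))
    if not logs:
        return 1e-8
    dof = max(1, len(logs) - len(_FREE_PARAMS))
    return max(float(np.sqrt(np.sum(np.square(logs)) / dof)), 1e-8)


def confidence_intervals(
    fit: InfusionNetworkFit,
    n_boot: int = 200,
    seed: int = 0,
    noise_cv: float | None = None,
) -> InfusionNetworkFit:
    """95% parametric-bootstrap confidence intervals per edge.

    The observed enrichments are resampled with multiplicative lognormal
    noise at the measurement scale (``noise_cv``, or estimated from the fit
    residuals), the network is refitted from the best fit for each
    resample, and the 2.5/97.5 percentiles are taken per edge (and for the
    TCA loss factor).  Perturbing the measured data — rather than the
    fitted predictions — keeps the interval honest when the estimator's
    spread scales with the flux magnitude, as it does under multiplicative
    noise.  Deterministic for a given seed and ``n_boot``.
    """
    if n_boot < 40:
        warnings.warn("n_boot < 40: bootstrap percentiles are unstable", stacklevel=2)
    rng = np.random.default_rng(seed)
    sigma = noise_cv if noise_cv is not None else _estimate_noise_scale(fit)
    params = fit.best_fit.free_params()
    upper = 10.0 * max(
        fit.fcircs[node].fcirc * NODE_CARBONS[node] for node in NODES
    )
    lower_b = np.zeros(5)
    upper_b = np.array([upper] * 4 + [1.0])
    x0 = np.clip(params, lower_b + 1e-12, upper_b - 1e-12)

    draws = []
    for _ in range(n_boot):
        boot_exps = []
        for exp in fit.experiments:
            node = exp.infused_node
            noisy = {}
            for obs_node, value in exp.steady_state_enrichments.items():
                if value > 1e-12:
                    value = float(
                        np.clip(value * np.exp(sigma * rng.standard_normal()), 1e-9, 0.999)
                    )
                else:
                    value = 0.0
                noisy[obs_node] = value
            noisy[node] = max(noisy.get(node, 1e-6), 1e-6)
            boot_exps.append(dataclasses.replace(exp, steady_state_enrichments=noisy))
        boot_fcircs = {
            e.infused_node: compute_fcirc(e) for e in boot_exps
        }
        refit = optimize.least_squares(
            _residuals,
            x0,
            args=(tuple(boot_exps), boot_fcircs),
            bounds=(lower_b, upper_b),
            xtol=1e-12,
            ftol=1e-12,
        )
        network = FluxNetwork.from_free_params(*_clip_feasible(refit.x))
        sample = network.edge_fluxes()
        sample["tca_loss"] = network.tca_loss
        draws.append(sample)

    estimates = fit.estimates()
    keys = list(estimates)
    matrix = np.array([[d[k] for k in keys] for d in draws])
    lo = np.percentile(matrix, 2.5, axis=0)
    hi = np.percentile(matrix, 97.5, axis=0)
    ci_lower = {k: float(min(lo[i], estimates[k])) for i, k in enumerate(keys)}
    ci_upper = {k: float(max(hi[i], estimates[k])) for i, k in enumerate(keys)}
    return dataclasses.replace(
        fit, ci_lower=ci_lower, ci_upper=ci_upper, noise_scale=float(sigma)
    )
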
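"""Competing demographic scenarios for the origin of ecotype pairs.

Two locally adapted ecotypes ("crab" and "wave") sampled in two localities
(or two regions) may have arisen either *in parallel*, after an ancestral
population colonised the localities, or from a single *old divergence* that
predates colonisation, possibly with an initial allopatric phase.  Each
hypothesis exists in a within-region flavour (with an unsampled "ghost"
meta-population absorbing local gene flow) and a between-region flavour
(no ghost; the locality sample represents its regional meta-population).

This module defines the prior specifications for the model parameters,
draws parameter records honouring the models' time-ordering constraints,
and converts a record into an executable :class:`DemographicScenario` —
a list of demes, migration epochs, and merge/resize events read backward
from the present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "MODELS",
    "PriorSpec",
    "WithinRegionParams",
    "BetweenRegionParams",
    "Deme",
    "Epoch",
    "DemographicEvent",
    "DemographicScenario",
    "default_priors",
    "draw_parameters",
    "params_from_record",
    "build_scenario",
    "build_parallel_within",
    "build_old_within",
    "build_parallel_between",
    "build_old_between",
]

#: The four competing models: divergence mode x geographic scale.
MODELS = ("parallel_within", "old_within", "parallel_between", "old_between")


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """A univariate prior: log-uniform or uniform on (lower, upper)."""

    name: str
    kind: str  # "log_uniform" | "uniform"
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.kind not in ("log_uniform", "uniform"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower must be < upper")
        if self.kind == "log_uniform" and self.lower <= 0:
            raise ValueError(f"{self.name}: log-uniform requires lower > 0")

    def sample(self, rng: np.random.Generator, size=None):
        if self.kind == "log_uniform":
            return np.exp(rng.uniform(math.log(self.lower), math.log(self.upper), size))
        return rng.uniform(self.lower, self.upper, size)

    def logpdf(self, x: float) -> float:
        if not (self.lower <= x <= self.upper):
            return -math.inf
        if self.kind == "log_uniform":
            return -math.log(x) - math.log(math.log(self.upper / self.lower))
        return -math.log(self.upper - self.lower)


# Default ranges bracket the posterior medians reported for this system
# (local sizes ~1e4, ghost sizes ~1e6, split times 1e4-1e6 generations,
# migration probabilities 1e-8..1e-5 per generation).  Mutation rates span
# one order of magnitude below the fixed mitochondrial rate of 1.5e-8 and
# are uniform, as are the dimensionless time proportions.
_SIZE = ("log_uniform", 1e2, 1e7)
_TIME = ("log_uniform", 1e2, 1e7)
_MIG = ("log_uniform", 1e-9, 1e-3)
_PROP = ("uniform", 1e-6, 1.0)
_MU = ("uniform", 1.5e-9, 1.5e-8)

_PRIOR_TABLE = {
    "parallel_within": ("Ng", "Nl", "Tlg", "PROPT", "Mlg", "Mwc", "MU", "AFLPMU"),
    "old_within": ("Ng", "Nl", "Twc", "PROPTlg", "PROPmig", "Mlg", "Mwc", "MU", "AFLPMU"),
    "parallel_between": ("Nl", "APS", "Tx", "PROPT", "Mx", "Mwc", "MU", "AFLPMU"),
    "old_between": ("Nl", "APS", "Twc", "PROPTx", "PROPmig", "Mx", "Mwc", "MU", "AFLPMU"),
}

_PRIOR_KINDS = {
    "Ng": _SIZE, "Nl": _SIZE,
    "Tlg": _TIME, "Twc": _TIME, "Tx": _TIME,
    "PROPT": _PROP, "PROPTlg": _PROP, "PROPTx": _PROP, "PROPmig": _PROP,
    "Mlg": _MIG, "Mwc": _MIG, "Mx": _MIG,
    "APS": ("log_uniform", 0.1, 100.0),
    "MU": _MU, "AFLPMU": _MU,
}


def default_priors(model: str) -> dict[str, PriorSpec]:
    """Default prior set for one of the four models (all configurable)."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    out = {}
    for name in _PRIOR_TABLE[model]:
        kind, lo, hi = _PRIOR_KINDS[name]
        out[name] = PriorSpec(name, kind, lo, hi)
    return out


# ---------------------------------------------------------------------------
# Parameter records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WithinRegionParams:
    """Within-region model parameters (ghost meta-population included).

    Sizes are diploid individuals, times generations before present,
    migration values per-generation per-lineage probabilities.
    """

    Ng: float
    Nl: float
    Tlg: float
    Twc: float
    Mlg: float
    Mwc: float
    MU: float
    AFLPMU: float
    Tmig: float | None = None  # old-divergence model only

    def __post_init__(self):
        if min(self.Ng, self.Nl) < 1:
            raise ValueError("effective sizes must be >= 1")
        if min(self.Tlg, self.Twc) <= 0:
            raise ValueError("times must be > 0")
        for m in (self.Mlg, self.Mwc):
            if not 0 <= m < 1:
                raise ValueError("migration probabilities must be in [0,1)")


@dataclass(frozen=True)
class BetweenRegionParams:
    """Between-region model parameters (no ghost; ancestral size = APS*Nl)."""

    Nl: float
    APS: float
    Tx: float
    Twc: float
    Mx: float
    Mwc: float
    MU: float
    AFLPMU: float
    Tmig: float | None = None

    def __post_init__(self):
        if self.Nl < 1 or self.APS * self.Nl < 1:
            raise ValueError("effective sizes must be >= 1")
        if min(self.Tx, self.Twc) <= 0:
            raise ValueError("times must be > 0")
        for m in (self.Mx, self.Mwc):
            if not 0 <= m < 1:
                raise ValueError("migration probabilities must be in [0,1)")


def _derive_times(model: str, rec: dict) -> dict:
    """Compute derived split times from the drawn time proportions.

    Proportions act on the natural-log scale: in the parallel models the
    ecotype split is Twc = Tlg**PROPT (within) or Tx**PROPT (between); in
    the old-divergence models the oldest event is the ecotype split Twc and
    the colonisation and end-of-allopatry times are Twc**PROPTlg (or
    **PROPTx) and Twc**PROPmig.
    """
    rec = dict(rec)
    if model == "parallel_within":
        rec["Twc"] = rec["Tlg"] ** rec["PROPT"]
    elif model == "parallel_between":
        rec["Twc"] = rec["Tx"] ** rec["PROPT"]
    elif model == "old_within":
        rec["Tlg"] = rec["Twc"] ** rec["PROPTlg"]
        rec["Tmig"] = rec["Twc"] ** rec["PROPmig"]
    elif model == "old_between":
        rec["Tx"] = rec["Twc"] ** rec["PROPTx"]
        rec["Tmig"] = rec["Twc"] ** rec["PROPmig"]
    else:
        raise ValueError(f"unknown model {model!r}")
    return rec


def _constraint_ok(model: str, rec: dict) -> bool:
    if model == "old_within":
        return rec["PROPmig"] > rec["PROPTlg"]  # equivalently Tmig > Tlg
    if model == "old_between":
        return rec["PROPmig"] > rec["PROPTx"]  # equivalently Tmig > Tx
    return True  # parallel models: Twc < T(lg|x) holds since PROPT < 1


def draw_parameters(
    model: str,
    priors: dict[str, PriorSpec],
    rng: np.random.Generator,
    max_tries: int = 10_000,
) -> dict:
    """Draw one parameter record; old-model draws violating the allopatry
    ordering (Tmig must postdate colonisation) are rejected and redrawn."""
    if not priors:
        raise ValueError("empty prior list")
    for _ in range(max_tries):
        rec = {name: float(spec.sample(rng)) for name, spec in priors.items()}
        rec = _derive_times(model, rec)
        if _constraint_ok(model, rec):
            rec["model"] = model
            return rec
    raise RuntimeError(f"constraint rejection did not accept a draw in {max_tries} tries")


def params_from_record(rec: dict) -> WithinRegionParams | BetweenRegionParams:
    model = rec["model"]
    if model.endswith("_within"):
        return WithinRegionParams(
            Ng=rec["Ng"], Nl=rec["Nl"], Tlg=rec["Tlg"], Twc=rec["Twc"],
            Mlg=rec["Mlg"], Mwc=rec["Mwc"], MU=rec["MU"], AFLPMU=rec["AFLPMU"],
            Tmig=rec.get("Tmig"),
        )
    return BetweenRegionParams(
        Nl=rec["Nl"], APS=rec["APS"], Tx=rec["Tx"], Twc=rec["Twc"],
        Mx=rec["Mx"], Mwc=rec["Mwc"], MU=rec["MU"], AFLPMU=rec["AFLPMU"],
        Tmig=rec.get("Tmig"),
    )


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Deme:
    name: str
    size: float  # diploid individuals
    sampled: bool = True


@dataclass(frozen=True)
class Epoch:
    """Half-open time interval [start, end) with a constant migration matrix
    of per-generation per-lineage probabilities (zero diagonal)."""

    start: float
    end: float  # math.inf for the terminal epoch
    migration: np.ndarray


@dataclass(frozen=True)
class DemographicEvent:
    time: float
    kind: str  # "merge" | "resize"
    source: int  # merged deme (merge) or resized deme (resize)
    dest: int = -1  # absorbing deme (merge only)
    size: float = -1.0  # new diploid size (resize only)


@dataclass(frozen=True)
class DemographicScenario:
    """Backward-time demography: demes, migration epochs, timed events."""

    model: str
    demes: tuple[Deme, ...]
    epochs: tuple[Epoch, ...]
    events: tuple[DemographicEvent, ...]
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    @property
    def n_demes(self) -> int:
        return len(self.demes)

    def validate(self) -> None:
        D = self.n_demes
        t = 0.0
        for ep in self.epochs:
            if not math.isclose(ep.start, t, rel_tol=1e-12, abs_tol=0.0) and ep.start != t:
                raise ValueError("epochs must tile [0, inf) without gaps")
            if ep.end < ep.start:
                raise ValueError("epoch end before start")
            M = np.asarray(ep.migration, dtype=float)
            if M.shape != (D, D):
                raise ValueError("migration matrix shape mismatch")
            if (M < 0).any() or np.diag(M).any():
                raise ValueError("migration entries must be >= 0 with zero diagonal")
            t = ep.end
        if not math.isinf(t):
            raise ValueError("final epoch must extend to infinity")
        alive = D
        last = 0.0
        for ev in self.events:
            if ev.time <= 0:
                raise ValueError("event times must be strictly positive")
            if ev.time < last:
                raise ValueError("events must be time-ordered")
            last = ev.time
            if ev.kind == "merge":
                alive -= 1
            elif ev.kind == "resize":
                if ev.size < 1:
                    raise ValueError("resize to size < 1")
            else:
                raise ValueError(f"unknown event kind {ev.kind!r}")
        if alive != 1:
            raise ValueError("after the final merge exactly one deme must remain")

    def compile(self) -> dict[str, np.ndarray]:
        """Flat array form consumed by the coalescent simulator."""
        E, D = len(self.epochs), self.n_demes
        mig = np.zeros((E, D, D))
        starts = np.zeros(E)
        for i, ep in enumerate(self.epochs):
            starts[i] = ep.start
            mig[i] = ep.migration
        ev_time = np.array([ev.time for ev in self.events], dtype=float)
        ev_kind = np.array([0 if ev.kind == "merge" else 1 for ev in self.events], dtype=np.int64)
        ev_a = np.array([ev.source for ev in self.events], dtype=np.int64)
        ev_b = np.array(
            [ev.dest if ev.kind == "merge" else -1 for ev in self.events], dtype=np.int64
        )
        ev_size = np.array(
            [ev.size if ev.kind == "resize" else -1.0 for ev in self.events], dtype=float
        )
        return {
            "sizes": np.array([d.size for d in self.demes], dtype=float),
            "epoch_starts": starts,
            "migration": mig,
            "ev_time": ev_time,
            "ev_kind": ev_kind,
            "ev_a": ev_a,
            "ev_b": ev_b,
            "ev_size": ev_size,
        }

    def event_table(self) -> str:
        """Human-readable TSV of the scenario's timed events."""
        lines = ["time\tevent\tdemes"]
        for ev in self.events:
            if ev.kind == "merge":
                desc = f"{self.demes[ev.source].name}->{self.demes[ev.dest].name}"
            else:
                desc = f"{self.demes[ev.source].name}:size={ev.size:g}"
            lines.append(f"{ev.time:.6g}\t{ev.kind}\t{desc}")
        return "\n".join(lines) + "\n"


def _mat(D: int, pairs: Sequence[tuple[int, int, float]]) -> np.ndarray:
    M = np.zeros((D, D))
    for i, j, m in pairs:
        M[i, j] = m
        M[j, i] = m
    return M


def build_parallel_within(p: WithinRegionParams) -> DemographicScenario:
    """Parallel divergence within a region.

    Forward in time: an ancestral/ghost population (size Ng) colonises two
    localities (size Nl each) at Tlg; ecotypes then diverge within each
    locality at Twc with ongoing gene flow Mwc between ecotypes and Mlg
    between each local deme and the ghost.  No direct locality-locality
    migration.  Demes: loc1-crab, loc1-wave, loc2-crab, loc2-wave, ghost.
    """
    if not p.Twc < p.Tlg:
        raise ValueError("parallel model requires Twc < Tlg")
    D = 5
    demes = (
        Deme("loc1-crab", p.Nl), Deme("loc1-wave", p.Nl),
        Deme("loc2-crab", p.Nl), Deme("loc2-wave", p.Nl),
        Deme("ghost", p.Ng, sampled=False),
    )
    m0 = _mat(D, [(0, 1, p.Mwc), (2, 3, p.Mwc),
                  (0, 4, p.Mlg), (1, 4, p.Mlg), (2, 4, p.Mlg), (3, 4, p.Mlg)])
    m1 = _mat(D, [(0, 4, p.Mlg), (2, 4, p.Mlg)])
    epochs = (
        Epoch(0.0, p.Twc, m0),
        Epoch(p.Twc, p.Tlg, m1),
        Epoch(p.Tlg, math.inf, np.zeros((D, D))),
    )
    events = (
        DemographicEvent(p.Twc, "merge", source=1, dest=0),
        DemographicEvent(p.Twc, "merge", source=3, dest=2),
        DemographicEvent(p.Tlg, "merge", source=0, dest=4),
        DemographicEvent(p.Tlg, "merge", source=2, dest=4),
    )
    return DemographicScenario("parallel_within", demes, epochs, events)


def build_old_within(p: WithinRegionParams) -> DemographicScenario:
    """Old divergence within a region.

    Forward in time: the ancestral population (size Ng) splits into crab
    and wave ghost meta-populations at Twc; they stay allopatric until
    Tmig, then exchange migrants at Mwc; each ghost founds its local deme
    at Tlg, after which local ecotype demes exchange Mwc within a locality
    and Mlg with their own-ecotype ghost.  Requires Tlg < Tmig < Twc.
    """
    if p.Tmig is None:
        raise ValueError("old-divergence model requires Tmig")
    if not (p.Tlg < p.Tmig <= p.Twc):
        raise ValueError("old model requires Tlg < Tmig <= Twc")
    D = 6
    demes = (
        Deme("loc1-crab", p.Nl), Deme("loc1-wave", p.Nl),
        Deme("loc2-crab", p.Nl), Deme("loc2-wave", p.Nl),
        Deme("crab-ghost", p.Ng, sampled=False),
        Deme("wave-ghost", p.Ng, sampled=False),
    )
    m0 = _mat(D, [(0, 1, p.Mwc), (2, 3, p.Mwc),
                  (0, 4, p.Mlg), (2, 4, p.Mlg), (1, 5, p.Mlg), (3, 5, p.Mlg)])
    m1 = _mat(D, [(4, 5, p.Mwc)])
    epochs = [
        Epoch(0.0, p.Tlg, m0),
        Epoch(p.Tlg, p.Tmig, m1),
        Epoch(p.Tmig, p.Twc, np.zeros((D, D))),  # allopatric phase: no gene flow
        Epoch(p.Twc, math.inf, np.zeros((D, D))),
    ]
    events = (
        DemographicEvent(p.Tlg, "merge", source=0, dest=4),
        DemographicEvent(p.Tlg, "merge", source=2, dest=4),
        DemographicEvent(p.Tlg, "merge", source=1, dest=5),
        DemographicEvent(p.Tlg, "merge", source=3, dest=5),
        DemographicEvent(p.Twc, "merge", source=5, dest=4),
    )
    return DemographicScenario("old_within", demes, tuple(epochs), events)


def build_parallel_between(
    p: BetweenRegionParams, expansion: float | None = None
) -> DemographicScenario:
    """Parallel divergence between regions (no ghost demes).

    Regions separate at Tx from an ancestral population of size APS*Nl;
    ecotypes form within each region at Twc.  Mwc connects ecotypes within
    a region; Mx connects same-ecotype demes across regions.  ``expansion``
    optionally resizes the surviving pre-ecotype demes at Twc (off by
    default; population expansion at ecotype formation was not supported).
    """
    if not p.Twc < p.Tx:
        raise ValueError("parallel model requires Twc < Tx")
    D = 4
    demes = (
        Deme("region1-crab", p.Nl), Deme("region1-wave", p.Nl),
        Deme("region2-crab", p.Nl), Deme("region2-wave", p.Nl),
    )
    m0 = _mat(D, [(0, 1, p.Mwc), (2, 3, p.Mwc), (0, 2, p.Mx), (1, 3, p.Mx)])
    m1 = _mat(D, [(0, 2, p.Mx)])
    epochs = (
        Epoch(0.0, p.Twc, m0),
        Epoch(p.Twc, p.Tx, m1),
        Epoch(p.Tx, math.inf, np.zeros((D, D))),
    )
    events = [
        DemographicEvent(p.Twc, "merge", source=1, dest=0),
        DemographicEvent(p.Twc, "merge", source=3, dest=2),
    ]
    if expansion is not None:
        events += [
            DemographicEvent(p.Twc, "resize", source=0, size=expansion),
            DemographicEvent(p.Twc, "resize", source=2, size=expansion),
        ]
    events += [
        DemographicEvent(p.Tx, "merge", source=2, dest=0),
        DemographicEvent(p.Tx, "resize", source=0, size=p.APS * p.Nl),
    ]
    return DemographicScenario("parallel_between", demes, epochs, tuple(events))


def build_old_between(p: BetweenRegionParams) -> DemographicScenario:
    """Old divergence between regions.

    Backward in time: regions merge within each ecotype at Tx; the two
    ecotype lineages exchange Mwc until Tmig, are allopatric on [Tmig, Twc),
    and merge into the ancestral population (size APS*Nl) at Twc.
    Requires Tx < Tmig < Twc.
    """
    if p.Tmig is None:
        raise ValueError("old-divergence model requires Tmig")
    if not (p.Tx < p.Tmig <= p.Twc):
        raise ValueError("old model requires Tx < Tmig <= Twc")
    D = 4
    demes = (
        Deme("region1-crab", p.Nl), Deme("region1-wave", p.Nl),
        Deme("region2-crab", p.Nl), Deme("region2-wave", p.Nl),
    )
    m0 = _mat(D, [(0, 1, p.Mwc), (2, 3, p.Mwc), (0, 2, p.Mx), (1, 3, p.Mx)])
    m1 = _mat(D, [(0, 1, p.Mwc)])
    epochs = (
        Epoch(0.0, p.Tx, m0),
        Epoch(p.Tx, p.Tmig, m1),
        Epoch(p.Tmig, p.Twc, np.zeros((D, D))),
        Epoch(p.Twc, math.inf, np.zeros((D, D))),
    )
    events = (
        DemographicEvent(p.Tx, "merge", source=2, dest=0),
        DemographicEvent(p.Tx, "merge", source=3, dest=1),
        DemographicEvent(p.Twc, "merge", source=1, dest=0),
        DemographicEvent(p.Twc, "resize", source=0, size=p.APS * p.Nl),
    )
    return DemographicScenario("old_between", demes, epochs, events)


_BUILDERS = {
    "parallel_within": build_parallel_within,
    "old_within": build_old_within,
    "parallel_between": build_parallel_between,
    "old_between": build_old_between,
}


def build_scenario(rec: dict) -> DemographicScenario:
    """Build the scenario for a parameter record produced by
    :func:`draw_parameters` (the record's ``model`` key selects the builder)."""
    params = params_from_record(rec)
    scen = _BUILDERS[rec["model"]](params)
    return replace(scen, params=dict(rec))
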
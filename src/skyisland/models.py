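"""Demographic models and the model catalogue used for inference.

A :class:`DemographicModel` describes 2 or 3 populations that split from a
common ancestor while exchanging migrants: current diploid effective sizes,
per-generation exponential growth rates, a forward migration matrix, and a
list of timed events (divergence joins and instantaneous size changes).
Time is measured in generations before present; sizes are diploid Ne.

The migration convention follows the forward-in-time reading of "M A to B":
``migration[i, j]`` is the per-generation probability that an individual in
population *j* originated in population *i*.  Backwards in time this is the
rate at which an ancestral lineage currently in *j* jumps to *i*, which is
how the coalescent engine consumes it.

The catalogue (:func:`build_model`) enumerates the ten two-population
divergence scenarios used for model selection (i–x) plus a three-population
variant, each paired with a :class:`ParameterSpace` of free parameters and
search bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Event",
    "DemographicModel",
    "Parameter",
    "ParameterSpace",
    "build_model",
    "CATALOGUE_IDS",
]

#: per-generation mutation rate used for passerines
MU_PASSERINE = 3e-9
#: per-generation mutation rate used for the kingfisher (non-passerine)
MU_KINGFISHER = 2e-9
#: generation time in years used for time scaling
GENERATION_TIME = 2.0


@dataclass(frozen=True)
class Event:
    """A timed demographic event (backwards in time).

    kind "join": all lineages in ``pop`` move into ``dest`` at ``time``;
    ``size`` (if given) resets the size of ``dest`` at that time (the
    ancestral Ne).  kind "size_change": the size of ``pop`` becomes ``size``
    for all times older than ``time`` (growth stops there).
    """

    time: float
    kind: str  # "join" | "size_change"
    pop: str
    dest: str | None = None
    size: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("join", "size_change"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.time < 0:
            raise ValueError(f"event time must be >= 0, got {self.time}")
        if self.kind == "join" and self.dest is None:
            raise ValueError("join event requires a destination population")
        if self.kind == "size_change" and (self.size is None or self.size <= 0):
            raise ValueError(f"size_change event requires size > 0 (field 'size', got {self.size})")


@dataclass
class DemographicModel:
    """Populations, sizes, growth, migration and timed events."""

    labels: tuple[str, ...]
    ne: tuple[float, ...]
    migration: np.ndarray  # forward convention, see module docstring
    growth: tuple[float, ...] = ()
    events: tuple[Event, ...] = ()
    mu: float = MU_PASSERINE
    generation_time: float = GENERATION_TIME

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.ne = tuple(float(x) for x in self.ne)
        if not self.growth:
            self.growth = tuple(0.0 for _ in self.labels)
        self.growth = tuple(float(x) for x in self.growth)
        self.migration = np.asarray(self.migration, dtype=float)
        self.events = tuple(sorted(self.events, key=lambda e: e.time))
        self.validate()

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        npop = len(self.labels)
        if npop not in (1, 2, 3):
            raise ValueError(f"1-3 populations supported, got {npop} (field 'labels')")
        if len(set(self.labels)) != npop:
            raise ValueError("population labels must be unique (field 'labels')")
        if len(self.ne) != npop or any(x <= 0 for x in self.ne):
            raise ValueError(f"need {npop} positive current sizes (field 'ne', got {self.ne})")
        if len(self.growth) != npop:
            raise ValueError("growth must have one rate per population (field 'growth')")
        if self.migration.shape != (npop, npop):
            raise ValueError(f"migration must be {npop}x{npop} (field 'migration')")
        if np.any(self.migration < 0) or np.any(self.migration >= 1):
            raise ValueError("migration entries must lie in [0, 1) (field 'migration')")
        if self.mu <= 0:
            raise ValueError("mutation rate must be positive (field 'mu')")
        if self.generation_time <= 0:
            raise ValueError("generation time must be positive (field 'generation_time')")
        for ev in self.events:
            if ev.pop not in self.labels:
                raise ValueError(f"event names unknown population {ev.pop!r} (field 'events')")
            if ev.kind == "join" and ev.dest not in self.labels:
                raise ValueError(f"join destination {ev.dest!r} unknown (field 'events')")
        # every population except one must eventually join; joined pops may
        # not host later events
        gone: set[str] = set()
        for ev in self.events:
            if ev.pop in gone or (ev.kind == "join" and ev.dest in gone):
                raise ValueError(
                    f"event at t={ev.time} refers to population {ev.pop!r} "
                    "after it was joined away (field 'events')"
                )
            if ev.kind == "join":
                gone.add(ev.pop)
        if npop > 1 and len(gone) != npop - 1:
            raise ValueError(
                f"{npop} populations require {npop - 1} join events, got {len(gone)} (field 'events')"
            )

    # -- convenience ---------------------------------------------------
    @property
    def n_pops(self) -> int:
        return len(self.labels)

    @property
    def t_div(self) -> float:
        """Oldest divergence time in generations (the root split)."""
        joins = [e.time for e in self.events if e.kind == "join"]
        if not joins:
            raise ValueError("model has no divergence event")
        return max(joins)

    @property
    def ne_ancestral(self) -> float:
        """Size attached to the root join."""
        joins = [e for e in self.events if e.kind == "join"]
        root = max(joins, key=lambda e: e.time)
        if root.size is None:
            return self.ne[self.labels.index(root.dest)]
        return root.size

    def with_migration(self, migration: np.ndarray) -> "DemographicModel":
        return replace(self, migration=np.asarray(migration, dtype=float))

    # -- constructors --------------------------------------------------
    @classmethod
    def single_population(cls, ne: float, label: str = "pop0", growth: float = 0.0,
                          mu: float = MU_PASSERINE, generation_time: float = GENERATION_TIME,
                          ) -> "DemographicModel":
        return cls(labels=(label,), ne=(ne,), migration=np.zeros((1, 1)),
                   growth=(growth,), events=(), mu=mu, generation_time=generation_time)

    @classmethod
    def two_population(cls, ne1: float, ne2: float, ne_anc: float, t_div: float,
                       m12: float = 0.0, m21: float = 0.0,
                       growth: tuple[float, float] = (0.0, 0.0),
                       size_changes: tuple[tuple[float, int, float], ...] = (),
                       labels: tuple[str, str] = ("pop1", "pop2"),
                       mu: float = MU_PASSERINE,
                       generation_time: float = GENERATION_TIME) -> "DemographicModel":
        """Isolation-with-migration model for two populations.

        ``m12`` is the forward per-generation migration rate from population
        1 into population 2; ``size_changes`` is a tuple of
        ``(time, pop_index, past_size)`` instantaneous size changes.
        """
        mig = np.array([[0.0, m12], [m21, 0.0]])
        events = [Event(t_div, "join", labels[1], dest=labels[0], size=ne_anc)]
        for (t, ipop, past) in size_changes:
            if not 0 <= t <= t_div:
                raise ValueError(
                    f"size change at t={t} outside (0, t_div={t_div}) (field 'size_changes')")
            events.append(Event(t, "size_change", labels[ipop], size=past))
        return cls(labels=labels, ne=(ne1, ne2), migration=mig, growth=growth,
                   events=tuple(events), mu=mu, generation_time=generation_time)

    @classmethod
    def three_population(cls, ne: tuple[float, float, float], ne_anc_12: float,
                         ne_anc: float, t1: float, t2: float,
                         migration: np.ndarray | None = None,
                         labels: tuple[str, str, str] = ("pop1", "pop2", "pop3"),
                         mu: float = MU_PASSERINE,
                         generation_time: float = GENERATION_TIME) -> "DemographicModel":
        """Topology ((1,2),3): pops 1 and 2 join at ``t1``, the joint
        population and pop 3 join at ``t2`` (``t1 <= t2``)."""
        if t1 > t2:
            raise ValueError(f"t1={t1} must not exceed t2={t2} (field 't1')")
        if migration is None:
            migration = np.zeros((3, 3))
        events = (
            Event(t1, "join", labels[1], dest=labels[0], size=ne_anc_12),
            Event(t2, "join", labels[2], dest=labels[0], size=ne_anc),
        )
        return cls(labels=labels, ne=ne, migration=migration, events=events,
                   mu=mu, generation_time=generation_time)


# ---------------------------------------------------------------------------
# parameter space


@dataclass(frozen=True)
class Parameter:
    name: str
    lower: float
    upper: float
    log_scale: bool = True

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
            raise ValueError(f"bounds for {self.name} must be finite")
        if self.lower >= self.upper:
            raise ValueError(f"bounds for {self.name} must be ordered")
        if self.log_scale and self.lower <= 0:
            raise ValueError(f"log-scale parameter {self.name} needs positive bounds")


@dataclass
class ParameterSpace:
    """Free parameters with search bounds plus fixed assignments."""

    free: tuple[Parameter, ...]
    fixed: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.free)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.free)

    def sample(self, rng: np.random.Generator) -> dict:
        """Draw one starting point, log-uniform where flagged."""
        out = dict(self.fixed)
        for p in self.free:
            if p.log_scale:
                out[p.name] = 10 ** rng.uniform(math.log10(p.lower), math.log10(p.upper))
            else:
                out[p.name] = rng.uniform(p.lower, p.upper)
        return out

    def to_vector(self, values: dict) -> np.ndarray:
        x = np.empty(self.k)
        for i, p in enumerate(self.free):
            v = float(values[p.name])
            x[i] = math.log10(v) if p.log_scale else v
        return x

    def from_vector(self, x: np.ndarray) -> dict:
        out = dict(self.fixed)
        for i, p in enumerate(self.free):
            v = 10 ** x[i] if p.log_scale else float(x[i])
            out[p.name] = min(max(v, p.lower), p.upper)
        return out

    def clip_vector(self, x: np.ndarray) -> tuple[np.ndarray, bool]:
        lo = np.array([math.log10(p.lower) if p.log_scale else p.lower for p in self.free])
        hi = np.array([math.log10(p.upper) if p.log_scale else p.upper for p in self.free])
        clipped = np.clip(x, lo, hi)
        return clipped, bool(np.any(clipped != x))


# ---------------------------------------------------------------------------
# the model catalogue

# default search bounds: log-uniform, bracketing every published estimate by
# at least an order of magnitude
_NE_BOUNDS = (1e3, 1e7)
_T_BOUNDS = (1e2, 1e7)
_M_BOUNDS = (1e-10, 1e-2)
_GROWTH_BOUNDS = (-1e-3, 1e-3)
# size-change ratio past/current: bottleneck (decline toward present) > 1,
# sudden expansion (increase toward present) < 1
_RATIO_UP = (1.0, 1e3)
_RATIO_DOWN = (1e-3, 1.0)

CATALOGUE_IDS = ("i", "ii", "iii", "iv", "v", "vi", "vii", "viii", "ix", "x", "3pop")

_CATALOGUE_DOC = {
    "i": "null: no growth, no migration",
    "ii": "migration, no growth",
    "iii": "exponential growth, no migration",
    "iv": "exponential growth and migration",
    "v": "past size-change event (bottleneck), with migration",
    "vi": "past size-change event (bottleneck), no migration",
    "vii": "past size-change event (sudden expansion), with migration",
    "viii": "past size-change event (sudden expansion), no migration",
    "ix": "bottleneck in population 1, sudden expansion in population 2, with migration",
    "x": "sudden expansion in population 1, bottleneck in population 2, with migration",
    "3pop": "three populations ((1,2),3) with migration, no growth",
}


def _two_pop_space(migration: bool, growth: bool,
                   ratio1: tuple[float, float] | None = None,
                   ratio2: tuple[float, float] | None = None) -> ParameterSpace:
    free = [
        Parameter("ne1", *_NE_BOUNDS),
        Parameter("ne2", *_NE_BOUNDS),
        Parameter("ne_anc", *_NE_BOUNDS),
        Parameter("t_div", *_T_BOUNDS),
    ]
    fixed: dict = {}
    if migration:
        free += [Parameter("m12", *_M_BOUNDS), Parameter("m21", *_M_BOUNDS)]
    else:
        fixed.update(m12=0.0, m21=0.0)
    if growth:
        free += [Parameter("g1", *_GROWTH_BOUNDS, log_scale=False),
                 Parameter("g2", *_GROWTH_BOUNDS, log_scale=False)]
    else:
        fixed.update(g1=0.0, g2=0.0)
    if ratio1 is not None:
        free += [Parameter("t_event", *_T_BOUNDS),
                 Parameter("ratio1", *ratio1),
                 Parameter("ratio2", *ratio2)]
    return ParameterSpace(free=tuple(free), fixed=fixed)


def _instantiate_two_pop(values: dict, labels: tuple[str, str], mu: float,
                         generation_time: float) -> DemographicModel:
    t_div = values["t_div"]
    size_changes: list[tuple[float, int, float]] = []
    if "t_event" in values:
        # event strictly inside (0, t_div); past size = current * ratio
        t_ev = min(values["t_event"], 0.99 * t_div)
        size_changes = [(t_ev, 0, values["ne1"] * values["ratio1"]),
                        (t_ev, 1, values["ne2"] * values["ratio2"])]
    return DemographicModel.two_population(
        ne1=values["ne1"], ne2=values["ne2"], ne_anc=values["ne_anc"], t_div=t_div,
        m12=values.get("m12", 0.0), m21=values.get("m21", 0.0),
        growth=(values.get("g1", 0.0), values.get("g2", 0.0)),
        size_changes=tuple(size_changes), labels=labels,
        mu=mu, generation_time=generation_time)


def _instantiate_three_pop(values: dict, labels: tuple[str, str, str], mu: float,
                           generation_time: float) -> DemographicModel:
    t1 = values["t1"]
    t2 = max(values["t2"], t1)
    mig = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            if i != j:
                mig[i, j] = values.get(f"m{i + 1}{j + 1}", 0.0)
    return DemographicModel.three_population(
        ne=(values["ne1"], values["ne2"], values["ne3"]),
        ne_anc_12=values["ne_anc12"], ne_anc=values["ne_anc"],
        t1=t1, t2=t2, migration=mig, labels=labels,
        mu=mu, generation_time=generation_time)


@dataclass
class CatalogueEntry:
    """A catalogue model: parameter space plus a builder closure."""

    catalogue_id: str
    space: ParameterSpace
    labels: tuple[str, ...]
    mu: float
    generation_time: float
    description: str

    def instantiate(self, values: dict) -> DemographicModel:
        vals = dict(self.space.fixed)
        vals.update(values)
        if self.catalogue_id == "3pop":
            return _instantiate_three_pop(vals, self.labels, self.mu, self.generation_time)
        return _instantiate_two_pop(vals, self.labels, self.mu, self.generation_time)


def build_model(catalogue_id: str, pop_labels: tuple[str, ...] = ("pop1", "pop2"),
                mu: float = MU_PASSERINE,
                generation_time: float = GENERATION_TIME) -> CatalogueEntry:
    """Return the catalogue entry (template + parameter space) for one id.

    Two-population ids i-x follow the divergence catalogue: (i) no growth, no
    migration; (ii) adds migration; (iii) adds growth instead; (iv) both;
    (v)-(viii) add a single past instantaneous size-change event in both
    daughter populations (bottleneck variants v/vi, sudden-expansion
    variants vii/viii, with/without migration); (ix)/(x) combine a
    bottleneck in one population with a sudden expansion in the other.
    """
    if catalogue_id not in CATALOGUE_IDS:
        raise ValueError(
            f"unknown catalogue id {catalogue_id!r}; known ids: {', '.join(CATALOGUE_IDS)}")
    if catalogue_id == "3pop":
        if len(pop_labels) != 3:
            raise ValueError("3pop model requires three population labels")
        free = [Parameter("ne1", *_NE_BOUNDS), Parameter("ne2", *_NE_BOUNDS),
                Parameter("ne3", *_NE_BOUNDS), Parameter("ne_anc12", *_NE_BOUNDS),
                Parameter("ne_anc", *_NE_BOUNDS),
                Parameter("t1", *_T_BOUNDS), Parameter("t2", *_T_BOUNDS)]
        for i in range(1, 4):
            for j in range(1, 4):
                if i != j:
                    free.append(Parameter(f"m{i}{j}", *_M_BOUNDS))
        space = ParameterSpace(free=tuple(free))
        return CatalogueEntry("3pop", space, tuple(pop_labels), mu, generation_time,
                              _CATALOGUE_DOC["3pop"])
    if len(pop_labels) != 2:
        raise ValueError(f"catalogue id {catalogue_id!r} requires two population labels")
    migration = catalogue_id in ("ii", "iv", "v", "vii", "ix", "x")
    growth = catalogue_id in ("iii", "iv")
    ratio1 = ratio2 = None
    if catalogue_id in ("v", "vi"):
        ratio1 = ratio2 = _RATIO_UP        # bottleneck: larger in the past
    elif catalogue_id in ("vii", "viii"):
        ratio1 = ratio2 = _RATIO_DOWN      # expansion: smaller in the past
    elif catalogue_id == "ix":
        ratio1, ratio2 = _RATIO_UP, _RATIO_DOWN
    elif catalogue_id == "x":
        ratio1, ratio2 = _RATIO_DOWN, _RATIO_UP
    space = _two_pop_space(migration, growth, ratio1, ratio2)
    return CatalogueEntry(catalogue_id, space, tuple(pop_labels), mu, generation_time,
                          _CATALOGUE_DOC[catalogue_id])
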
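"""Demographic models: population trees with split times, Ne and migration bands.

A :class:`DemographicModel` is a rooted population tree.  Each population
(leaf or internal branch) carries a diploid effective size, constant over
the branch except where a piecewise trajectory is given.  Internal
populations are created at their split time (the time, going backwards,
at which their two child populations merge into them).  Migration bands
are directed channels of gene flow between two populations that coexist
over some interval; each band carries a *total* rate ``m_tot``, the
expected number of migration events per lineage over the coexistence
interval, so the per-generation rate is ``m = m_tot / duration``.

Models are serialized as YAML.  Times in the file are in years and sizes
in diploid individuals; internally all times are generations (converted
through ``generation_time``), and years appear only at I/O boundaries.

Band direction convention: a band ``source -> target`` describes
forward-in-time gene flow from ``source`` into ``target``.  Backwards in
time (the direction the coalescent simulator runs) a lineage currently in
``target`` therefore moves into ``source``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import InvalidParameterError, ModelError

__all__ = [
    "Population",
    "MigrationBand",
    "PiecewiseNeTrajectory",
    "DemographicModel",
    "load_model",
    "bundled_model",
]


@dataclass(frozen=True)
class PiecewiseNeTrajectory:
    """Piecewise-constant Ne along a single branch.

    ``breakpoints`` are times in generations before present, ascending;
    ``ne_values`` has one more entry than ``breakpoints`` (the size in
    each epoch, present-day first).
    """

    breakpoints: tuple[float, ...]
    ne_values: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "breakpoints", tuple(float(b) for b in self.breakpoints))
        object.__setattr__(self, "ne_values", tuple(float(n) for n in self.ne_values))
        if len(self.ne_values) != len(self.breakpoints) + 1:
            raise InvalidParameterError(
                "need exactly one more Ne value than breakpoints"
            )
        if any(n <= 0 for n in self.ne_values):
            raise InvalidParameterError("all Ne values must be > 0")
        if any(b <= 0 for b in self.breakpoints):
            raise InvalidParameterError("breakpoints must be > 0")
        if list(self.breakpoints) != sorted(self.breakpoints):
            raise InvalidParameterError("breakpoints must be ascending")

    def ne_at(self, t: float) -> float:
        """Ne in effect at time ``t`` generations before present."""
        for b, n in zip(self.breakpoints, self.ne_values):
            if t < b:
                return n
        return self.ne_values[-1]


@dataclass
class Population:
    """One branch of the population tree.

    ``start_gen`` is when the population comes into existence looking
    backwards (0 for sampled leaves, the split time for internal
    branches); ``end_gen`` is when it merges into its parent (inf for the
    root).  ``ne`` is a constant diploid size or a trajectory.
    """

    name: str
    parent: str | None
    ne: float | PiecewiseNeTrajectory
    start_gen: float = 0.0
    end_gen: float = float("inf")

    def ne_at(self, t: float) -> float:
        if isinstance(self.ne, PiecewiseNeTrajectory):
            return self.ne.ne_at(t)
        return self.ne

    @property
    def is_leaf(self) -> bool:
        return self.start_gen == 0.0


@dataclass(frozen=True)
class MigrationBand:
    """Directed forward-time gene flow channel with total rate m_tot."""

    source: str
    target: str
    m_tot: float

    def __post_init__(self):
        if self.m_tot < 0:
            raise InvalidParameterError("m_tot must be >= 0")


class DemographicModel:
    """Population tree with split times, per-branch Ne and migration bands."""

    def __init__(
        self,
        populations: dict[str, Population],
        migration_bands: list[MigrationBand] | None = None,
        generation_time: float = 3.0,
        mutation_rate: float = 1e-8,
        name: str = "model",
    ):
        self.populations = populations
        self.migration_bands = list(migration_bands or [])
        self.generation_time = float(generation_time)
        self.mutation_rate = float(mutation_rate)
        self.name = name
        self._validate()

    # -- structure ---------------------------------------------------------
    def _validate(self) -> None:
        roots = [p for p in self.populations.values() if p.parent is None]
        if len(roots) != 1:
            raise ModelError(f"model must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        children: dict[str, list[str]] = {}
        for p in self.populations.values():
            if p.parent is not None:
                if p.parent not in self.populations:
                    raise ModelError(f"unknown parent {p.parent!r} of {p.name!r}")
                children.setdefault(p.parent, []).append(p.name)
                if p.end_gen <= p.start_gen:
                    raise ModelError(
                        f"population {p.name!r} has empty lifetime "
                        f"[{p.start_gen}, {p.end_gen})"
                    )
        self.children = children
        for name, kids in children.items():
            if len(kids) not in (1, 2):
                raise ModelError(
                    f"internal population {name!r} must have 1 or 2 children"
                )
            parent = self.populations[name]
            for k in kids:
                if self.populations[k].end_gen != parent.start_gen:
                    raise ModelError(
                        f"child {k!r} must end at parent's split time "
                        f"({parent.start_gen})"
                    )
        # split times strictly increase root-ward
        for p in self.populations.values():
            if p.parent is not None:
                parent = self.populations[p.parent]
                if parent.start_gen <= p.start_gen:
                    raise ModelError(
                        f"split times must strictly increase root-ward "
                        f"({p.name}: {p.start_gen} vs {p.parent}: {parent.start_gen})"
                    )
        for band in self.migration_bands:
            for end in (band.source, band.target):
                if end not in self.populations:
                    raise ModelError(f"migration band references unknown {end!r}")
            if self.band_interval(band) is None:
                raise ModelError(
                    f"band {band.source}->{band.target}: populations never coexist"
                )

    @property
    def leaves(self) -> list[str]:
        return [p.name for p in self.populations.values() if p.is_leaf]

    def band_interval(self, band: MigrationBand) -> tuple[float, float] | None:
        """Coexistence interval (generations) of a band's two populations."""
        a = self.populations[band.source]
        b = self.populations[band.target]
        lo = max(a.start_gen, b.start_gen)
        hi = min(a.end_gen, b.end_gen)
        return (lo, hi) if hi > lo else None

    def band_rate(self, band: MigrationBand) -> float:
        """Per-generation, per-lineage migration rate of a band."""
        lo, hi = self.band_interval(band)
        if hi == float("inf"):
            raise ModelError("band on root-adjacent infinite interval needs finite span")
        return band.m_tot / (hi - lo)

    def without_migration(self) -> "DemographicModel":
        """Copy of this model with all migration bands removed."""
        return DemographicModel(
            dict(self.populations),
            [],
            generation_time=self.generation_time,
            mutation_rate=self.mutation_rate,
            name=self.name + "_nomig",
        )

    def with_leaf_ne(self, ne: float) -> "DemographicModel":
        """Copy with every leaf population set to a constant Ne."""
        pops = {}
        for name, p in self.populations.items():
            if p.is_leaf:
                pops[name] = Population(name, p.parent, float(ne), p.start_gen, p.end_gen)
            else:
                pops[name] = p
        return DemographicModel(
            pops, self.migration_bands, self.generation_time, self.mutation_rate, self.name
        )

    def epoch_boundaries(self) -> list[float]:
        """All times at which simulation rates can change (sorted, > 0)."""
        times: set[float] = set()
        for p in self.populations.values():
            if p.start_gen > 0:
                times.add(p.start_gen)
            if isinstance(p.ne, PiecewiseNeTrajectory):
                times.update(p.ne.breakpoints)
        for band in self.migration_bands:
            lo, hi = self.band_interval(band)
            if lo > 0:
                times.add(lo)
            if hi < float("inf"):
                times.add(hi)
        return sorted(times)

    # -- serialization -----------------------------------------------------
    @classmethod
    def from_dict(cls, cfg: dict) -> "DemographicModel":
        gen_time = float(cfg.get("generation_time", 3.0))
        mu = float(cfg.get("mutation_rate", 1e-8))
        raw = {p["name"]: p for p in cfg["populations"]}
        # split_years on an internal node = time its children merge into it
        start = {}
        for name, p in raw.items():
            sy = p.get("split_years")
            start[name] = float(sy) / gen_time if sy is not None else 0.0
        pops: dict[str, Population] = {}
        for name, p in raw.items():
            parent = p.get("parent")
            end = start[parent] if parent is not None else float("inf")
            ne = p["ne"]
            if isinstance(ne, (list, tuple)):
                bps = [float(b) / gen_time for b in p["ne_breakpoints_years"]]
                ne = PiecewiseNeTrajectory(tuple(bps), tuple(float(n) for n in ne))
            else:
                ne = float(ne)
                if ne <= 0:
                    raise ModelError(f"population {name!r}: Ne must be > 0")
            pops[name] = Population(name, parent, ne, start[name], end)
        bands = [
            MigrationBand(b["source"], b["target"], float(b["m_tot"]))
            for b in cfg.get("migration_bands", [])
        ]
        return cls(pops, bands, gen_time, mu, name=cfg.get("name", "model"))

    def to_dict(self) -> dict:
        pops = []
        for p in self.populations.values():
            entry: dict = {"name": p.name, "parent": p.parent}
            if isinstance(p.ne, PiecewiseNeTrajectory):
                entry["ne"] = list(p.ne.ne_values)
                entry["ne_breakpoints_years"] = [
                    b * self.generation_time for b in p.ne.breakpoints
                ]
            else:
                entry["ne"] = p.ne
            if p.start_gen > 0:
                entry["split_years"] = p.start_gen * self.generation_time
            pops.append(entry)
        return {
            "name": self.name,
            "generation_time": self.generation_time,
            "mutation_rate": self.mutation_rate,
            "populations": pops,
            "migration_bands": [
                {"source": b.source, "target": b.target, "m_tot": b.m_tot}
                for b in self.migration_bands
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_model(path: str | Path) -> DemographicModel:
    """Load a demographic model from a YAML config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return DemographicModel.from_dict(cfg)


def bundled_model(name: str) -> DemographicModel:
    """Load one of the bundled models: fig5a, regional, isw_source."""
    ref = resources.files("canid_popgen.data").joinpath(f"{name}.yaml")
    cfg = yaml.safe_load(ref.read_text())
    return DemographicModel.from_dict(cfg)
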
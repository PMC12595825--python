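"""Forward-time haploid simulator of Y-STR haplotypes.

Simulates multilocus STR haplotypes evolving under Wright-Fisher haploid
reproduction with strict single-step mutation (each locus mutates with
probability mu per generation to +-1 repeat, equal probability), the model
assumed by R_ST and rho. Demographies cover the five topologies used for
migration-model comparison — panmixia, an east-to-west chain with
unidirectional gene flow, divergence from a common ancestor, divergence
with ongoing unidirectional migration, and divergence with bidirectional
migration — plus admixture pulses from a deeply diverged HOST deme
(emulating introgression of local host-population lineages such as R1b
into a founder population).

Every sampled individual carries a truth label (FOUNDER vs HOST lineage)
and the realised migrant counts and founder depths are recorded, so
estimator-recovery tests can compare inferences against known truth.

Internally each of the 17 panel markers is an independent mutating unit;
the composite DYS389II is reported as DYS389I plus its own unit, so the
containment convention holds and the NETWORK/RHO view recovers 15
independent loci at rate mu.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .io import REGIONS, YFILER17, Dataset, Haplotype

__all__ = [
    "MODELS",
    "ScenarioConfig",
    "SimTruth",
    "simulate",
    "scenario_library",
    "founder_star",
]

MODELS = (
    "PANMIXIA",
    "CHAIN_EAST_WEST",
    "DIVERGENCE",
    "DIVERGENCE_MIGRATION",
    "DIVERGENCE_BIDIR",
)

#: Founder repeat counts for the 17 internal mutating units (modal human
#: Yfiler alleles; the DYS389II entry is the II-minus-I part).
_BASE_ALLELES = {
    "DYS19": 14,
    "DYS389I": 13,
    "DYS389II": 16,  # the 'b' part; reported DYS389II = DYS389I + this
    "DYS390": 24,
    "DYS391": 10,
    "DYS392": 11,
    "DYS393": 13,
    "DYS385a": 11,
    "DYS385b": 14,
    "DYS437": 15,
    "DYS438": 10,
    "DYS439": 12,
    "DYS448": 19,
    "DYS456": 15,
    "DYS458": 16,
    "DYS635": 23,
    "YGATAH4": 12,
}

FOUNDER = "FOUNDER"
HOST = "HOST"


@dataclass
class ScenarioConfig:
    """Demographic scenario for the forward simulator.

    ``split_time`` is generations before present at which labelled demes
    are founded from the ancestral deme (chain/panmixia demes are founded
    at the same depth without subsequent isolation). ``migration`` is the
    per-individual per-generation immigration probability applied along the
    model's topology. ``admixture_pulses`` are (target, time, fraction)
    replacement events from the HOST deme.
    """

    model: str = "DIVERGENCE"
    pop_labels: tuple[str, ...] = REGIONS
    pop_sizes: dict = field(default_factory=dict)  # label -> haploid N
    split_time: int = 20
    migration: float = 0.0
    admixture_pulses: list = field(default_factory=list)  # dicts: target, time, fraction
    loci: int = 17
    mu: float = 2.5e-3
    range_constraint: Optional[tuple[int, int]] = None
    seed: int = 0
    burn_in: int = 500
    sample_sizes: dict = field(default_factory=dict)
    host_size: int = 200
    host_divergence: int = 2000
    default_pop_size: int = 250

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        self.pop_labels = tuple(self.pop_labels)
        for p in self.pop_labels:
            self.pop_sizes.setdefault(p, self.default_pop_size)
        for p in self.pop_labels:
            self.sample_sizes.setdefault(p, min(50, self.pop_sizes[p]))
            if self.sample_sizes[p] > self.pop_sizes[p]:
                raise ValueError(f"sample size > deme size for {p}")
        for pulse in self.admixture_pulses:
            if not 0 <= pulse["fraction"] <= 1:
                raise ValueError("pulse fraction must be in [0, 1]")
            if pulse["time"] > self.split_time:
                raise ValueError("pulse predates the deme it targets")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        if "pop_labels" in data:
            data["pop_labels"] = tuple(data["pop_labels"])
        if data.get("range_constraint") is not None:
            data["range_constraint"] = tuple(data["range_constraint"])
        return cls(**data)


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated dataset."""

    genealogy_tmrca: dict
    realized_migrants: dict
    haplogroup_labels: dict
    scenario: dict

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {
                "genealogy_tmrca": self.genealogy_tmrca,
                "realized_migrants": {f"{a}->{b}": c for (a, b), c in self.realized_migrants.items()},
                "haplogroup_labels": self.haplogroup_labels,
                "scenario": self.scenario,
            },
            indent=2,
        ))


def _mutate(X: np.ndarray, mu: float, rng: np.random.Generator,
            bounds: Optional[tuple[int, int]]) -> np.ndarray:
    mask = rng.random(X.shape) < mu
    steps = rng.integers(0, 2, size=X.shape) * 2 - 1
    X = X + mask * steps
    if bounds is not None:
        lo, hi = bounds
        X = np.where(X < lo, 2 * lo - X, X)  # single-step reflection
        X = np.where(X > hi, 2 * hi - X, X)
    return X


def _wf_generation(X: np.ndarray, labels: np.ndarray, mu: float,
                   rng: np.random.Generator, bounds) -> tuple[np.ndarray, np.ndarray]:
    n = X.shape[0]
    parents = rng.integers(0, n, size=n)
    return _mutate(X[parents], mu, rng, bounds), labels[parents]


def _unit_names(loci: int) -> list[str]:
    names = list(YFILER17.loci)
    if loci <= len(names):
        return names[:loci]
    return names + [f"STR{k}" for k in range(loci - len(names))]


def simulate(config: ScenarioConfig) -> tuple[Dataset, SimTruth]:
    """Run the configured scenario and return the sampled dataset + truth."""
    rng = np.random.default_rng(config.seed)
    units = _unit_names(config.loci)
    base = np.asarray([_BASE_ALLELES.get(u, 14) for u in units], dtype=np.int64)
    bounds = config.range_constraint
    mu = config.mu
    tau = config.split_time
    labels = list(config.pop_labels)

    # ancestral deme: founded monomorphic, evolved for the burn-in
    n_anc = max(config.pop_sizes.values())
    anc = np.tile(base, (n_anc, 1))
    anc_lab = np.asarray([FOUNDER] * n_anc, dtype=object)
    for _ in range(config.burn_in):
        anc, anc_lab = _wf_generation(anc, anc_lab, mu, rng, bounds)

    # HOST deme: deeply diverged founder, realised by drawing its founder's
    # per-locus offset from the exact SMM displacement law at the
    # divergence depth, then evolving forward alongside the study demes
    need_host = bool(config.admixture_pulses)
    if need_host:
        nmut = rng.binomial(config.host_divergence, mu, size=len(units))
        offset = 2 * rng.binomial(nmut, 0.5) - nmut
        host = np.tile(base + offset, (config.host_size, 1))
        host_lab = np.asarray([HOST] * config.host_size, dtype=object)

    if config.model == "PANMIXIA":
        # one panmictic deme of the pooled size; labels are arbitrary
        total = sum(config.pop_sizes[p] for p in labels)
        X = anc[rng.integers(0, n_anc, size=total)]
        lab = np.asarray([FOUNDER] * total, dtype=object)
        demes = {"__pool__": (X, lab)}
        routes: list[tuple[str, str]] = []
    else:
        demes = {}
        for p in labels:
            n_p = config.pop_sizes[p]
            founders = rng.integers(0, n_anc, size=n_p)
            demes[p] = (anc[founders].copy(), anc_lab[founders].copy())
        if config.model == "DIVERGENCE":
            routes = []
        elif config.model in ("CHAIN_EAST_WEST", "DIVERGENCE_MIGRATION"):
            routes = [(labels[i], labels[i + 1]) for i in range(len(labels) - 1)]
        else:  # DIVERGENCE_BIDIR
            routes = [(labels[i], labels[i + 1]) for i in range(len(labels) - 1)]
            routes += [(b, a) for a, b in routes]

    migrants = {r: 0 for r in routes}
    pulses_by_time: dict[int, list] = {}
    for pulse in config.admixture_pulses:
        pulses_by_time.setdefault(int(pulse["time"]), []).append(pulse)

    for t in range(tau, 0, -1):
        for key in demes:
            X, lab = demes[key]
            demes[key] = _wf_generation(X, lab, mu, rng, bounds)
        if need_host:
            host, host_lab = _wf_generation(host, host_lab, mu, rng, bounds)
        for (src, dst) in routes:
            Xs, labs = demes[src]
            Xd, labd = demes[dst]
            nmig = rng.binomial(Xd.shape[0], config.migration)
            if nmig:
                targets = rng.choice(Xd.shape[0], size=nmig, replace=False)
                sources = rng.integers(0, Xs.shape[0], size=nmig)
                Xd[targets] = Xs[sources]
                labd[targets] = labs[sources]
                migrants[(src, dst)] += int(nmig)
        for pulse in pulses_by_time.get(t, []):
            dst = pulse["target"]
            Xd, labd = demes[dst]
            k = int(round(pulse["fraction"] * Xd.shape[0]))
            if k:
                targets = rng.choice(Xd.shape[0], size=k, replace=False)
                sources = rng.integers(0, host.shape[0], size=k)
                Xd[targets] = host[sources]
                labd[targets] = host_lab[sources]

    # terminal sampling
    haplotypes: list[Haplotype] = []
    truth_labels: dict[str, str] = {}
    i389 = units.index("DYS389I") if "DYS389I" in units else None
    j389 = units.index("DYS389II") if "DYS389II" in units else None
    for p in labels:
        if config.model == "PANMIXIA":
            X, lab = demes["__pool__"]
            offset = sum(config.sample_sizes[q] for q in labels[: labels.index(p)])
            pick = np.arange(offset, offset + config.sample_sizes[p])
        else:
            X, lab = demes[p]
            pick = rng.choice(X.shape[0], size=config.sample_sizes[p], replace=False)
        for k, i in enumerate(pick):
            row = X[i].copy()
            alleles = {}
            for j, u in enumerate(units):
                v = int(row[j])
                if j389 is not None and j == j389 and i389 is not None:
                    v = int(row[i389]) + v  # report the composite as the sum
                alleles[u] = float(max(v, 1))
            sid = f"{p}_{k:03d}"
            haplotypes.append(
                Haplotype(
                    sample_id=sid,
                    population=p,
                    region=p if p in REGIONS else None,
                    alleles=alleles,
                )
            )
            truth_labels[sid] = str(lab[i])

    panel = YFILER17 if config.loci == 17 else YFILER17.restrict(units)
    ds = Dataset(panel=panel, haplotypes=haplotypes,
                 provenance=f"simulated:{config.model}:seed={config.seed}")
    depth = {p: (config.burn_in + tau if config.model == "PANMIXIA" else tau) for p in labels}
    truth = SimTruth(
        genealogy_tmrca=depth,
        realized_migrants=migrants,
        haplogroup_labels=truth_labels,
        scenario=asdict(config),
    )
    return ds, truth


def scenario_library() -> dict[str, ScenarioConfig]:
    """Named presets: the five Iberian regional topologies plus the
    four-country east-to-west continental chain.

    Regional demes are the five Iberian regions in schematic east-to-west
    order; the regional split depth of 20 generations reflects the ~600
    years since the documented arrival in Iberia at ~30 y/generation, with
    small endogamous deme sizes (N = 250). The continental chain spans
    Greece → Romania → Slovakia → Spain with deeper splits (~35
    generations, the trans-European diaspora).
    """
    regional = dict(
        pop_labels=("East", "Centre", "North", "South", "West"),
        split_time=20,
        default_pop_size=250,
    )
    presets = {
        "iberia_panmixia": ScenarioConfig(model="PANMIXIA", **regional),
        "iberia_chain_east_west": ScenarioConfig(
            model="CHAIN_EAST_WEST", migration=0.02, **regional
        ),
        "iberia_divergence": ScenarioConfig(model="DIVERGENCE", **regional),
        "iberia_divergence_migration": ScenarioConfig(
            model="DIVERGENCE_MIGRATION", migration=0.02, **regional
        ),
        "iberia_divergence_bidir": ScenarioConfig(
            model="DIVERGENCE_BIDIR", migration=0.02, **regional
        ),
        "continental_chain": ScenarioConfig(
            model="CHAIN_EAST_WEST",
            pop_labels=("Greece", "Romania", "Slovakia", "Spain"),
            split_time=35,
            migration=0.02,
            default_pop_size=250,
        ),
    }
    return presets


def founder_star(
    n: int,
    depth: int,
    loci: int = 17,
    mu: float = 2.5e-3,
    seed: int = 0,
    population: str = "Star",
) -> tuple[Dataset, SimTruth]:
    """Star genealogy: n lineages descending independently from one founder
    exactly ``depth`` generations back.

    Per lineage and locus the number of mutations is Binomial(depth, mu)
    with independent +-1 steps — the exact law of the per-generation
    single-step process, drawn directly. Expected rho over L retained loci
    is depth x L x mu.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    units = _unit_names(loci)
    base = np.asarray([_BASE_ALLELES.get(u, 14) for u in units], dtype=np.int64)
    nmut = rng.binomial(depth, mu, size=(n, len(units)))
    disp = 2 * rng.binomial(nmut, 0.5) - nmut
    X = base + disp
    i389 = units.index("DYS389I") if "DYS389I" in units else None
    j389 = units.index("DYS389II") if "DYS389II" in units else None
    haplotypes = []
    truth_labels = {}
    for k in range(n):
        alleles = {}
        for j, u in enumerate(units):
            v = int(X[k, j])
            if j389 is not None and j == j389 and i389 is not None:
                v = int(X[k, i389]) + v
            alleles[u] = float(max(v, 1))
        sid = f"{population}_{k:03d}"
        haplotypes.append(Haplotype(sample_id=sid, population=population, alleles=alleles))
        truth_labels[sid] = FOUNDER
    panel = YFILER17 if loci == 17 else YFILER17.restrict(units)
    ds = Dataset(panel=panel, haplotypes=haplotypes, provenance=f"founder_star:seed={seed}")
    truth = SimTruth(
        genealogy_tmrca={population: depth},
        realized_migrants={},
        haplogroup_labels=truth_labels,
        scenario={"model": "STAR", "n": n, "depth": depth, "loci": loci, "mu": mu, "seed": seed},
    )
    return ds, truth
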
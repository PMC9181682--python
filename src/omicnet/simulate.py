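"""Synthetic multi-omic data with planted modules, hubs and trait effects.

The generator emulates the statistical structure of a two-strain (case vs
control, n per group small) proteomic + metabolomic study: log-normal raw
intensities, blocks of co-abundant features driven by shared latent factors,
a subset of blocks shifted between strains, and phenotype traits that are
linear functions of those latent factors.

Model
-----
For each planted module ``k`` and sample ``s`` a latent factor

    z_k(s) ~ Normal(delta_k * group(s), 1)

is drawn, where ``group(s)`` is the 0/1 strain indicator and ``delta_k`` the
module's between-strain shift (log2 units).  A member feature ``i`` of module
``k`` then has log2 abundance

    log2 x_i(s) = baseline + alpha_i * z_k(s) + Normal(0, noise_sd)

with ``alpha_i`` the member loading (one designated hub member gets an
elevated loading, which makes it both the most connected node and the feature
most correlated with the module's first principal component).  Background
features are baseline plus noise.  Raw intensities are ``2 ** log2x``;
metabolite entries are then masked missing completely at random at a
configurable rate, mimicking mass-spec dropouts.

Traits are linear in the latent factors plus Gaussian noise; the strain trait
is the exact 0/1 group label and seizure traits are forced to zero in every
control sample (controls are seizure-free by definition).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import METABOLITE, PROTEIN, OmicsMatrix, make_matrix

__all__ = [
    "PlantedModule",
    "SimConfig",
    "GroundTruth",
    "generate_dataset",
    "generate_pathways",
    "study_config",
]


@dataclass
class PlantedModule:
    """One planted co-abundance block.

    Parameters
    ----------
    name
        Label used in the ground truth (not the recovered color).
    size_proteins, size_metabolites
        Member counts drawn from each layer; total must be >= 3.
    loading
        Factor loading ``alpha`` of ordinary members; must be > 0.
    hub_loading
        Loading of the single designated hub member; must be >= ``loading``.
    group_effect
        Shift ``delta`` of the latent factor mean in the case group (log2 units).
    trait_effects
        Map trait name -> linear coefficient linking the latent factor to
        that trait.
    """

    name: str
    size_proteins: int
    size_metabolites: int
    loading: float = 1.0
    hub_loading: float = 1.5
    group_effect: float = 0.0
    trait_effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.size_proteins < 0 or self.size_metabolites < 0:
            raise ValueError(f"module {self.name}: negative member count")
        if self.size_proteins + self.size_metabolites < 3:
            raise ValueError(f"module {self.name}: needs >= 3 members")
        if self.loading <= 0:
            raise ValueError(f"module {self.name}: loading must be > 0")
        if self.hub_loading < self.loading:
            raise ValueError(f"module {self.name}: hub_loading must be >= loading")

    @property
    def size(self) -> int:
        return self.size_proteins + self.size_metabolites


@dataclass
class SimConfig:
    """Full description of one synthetic two-strain dataset."""

    n_per_group: int = 6
    n_proteins: int = 200
    n_metabolites: int = 100
    modules: list = field(default_factory=list)
    noise_sd: float = 1.0
    baseline_mean: float = 20.0
    missing_rate: float = 0.0
    trait_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")
        if not 0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must lie in [0, 0.5)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        need_p = sum(m.size_proteins for m in self.modules)
        need_m = sum(m.size_metabolites for m in self.modules)
        if need_p > self.n_proteins:
            raise ValueError(
                f"module protein demand {need_p} exceeds n_proteins {self.n_proteins}"
            )
        if need_m > self.n_metabolites:
            raise ValueError(
                f"module metabolite demand {need_m} exceeds n_metabolites {self.n_metabolites}"
            )
        names = [m.name for m in self.modules]
        if len(set(names)) != len(names):
            raise ValueError("module names must be unique")


@dataclass
class GroundTruth:
    """Planted structure of one generated dataset.

    ``assignments`` covers planted features only; everything else is
    background.  Exactly one hub per planted module.
    """

    assignments: dict  # feature -> module name
    hubs: dict  # module name -> hub feature
    trait_effects: dict  # module name -> {trait: coefficient}
    pathways: dict  # module name -> pathway-set name
    background: list  # non-planted feature IDs

    def members(self, module: str) -> list:
        return sorted(f for f, m in self.assignments.items() if m == module)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def study_config(seed: int = 0, **overrides) -> SimConfig:
    """The default study-like conditions: 6 vs 6 samples, five planted modules
    of sizes 15-40 (one seizure-associated disease module with a strong strain
    shift, an elevated-loading hub and trait links), moderate noise.
    """
    modules = [
        PlantedModule(
            name="disease",
            size_proteins=28,
            size_metabolites=12,
            loading=1.0,
            hub_loading=1.5,
            group_effect=2.0,
            trait_effects={
                "seizure_count": 1.0,
                "mean_seizure_duration": 1.0,
                "time_in_center": -1.0,
                "sucrose_preference": -1.0,
            },
        ),
        PlantedModule("mod2", 20, 10, loading=1.0, hub_loading=1.5),
        PlantedModule("mod3", 18, 7, loading=1.0, hub_loading=1.5),
        PlantedModule("mod4", 14, 6, loading=1.0, hub_loading=1.5),
        PlantedModule("mod5", 10, 5, loading=1.0, hub_loading=1.5),
    ]
    cfg = dict(
        n_per_group=6,
        n_proteins=200,
        n_metabolites=100,
        modules=modules,
        noise_sd=0.7,
        baseline_mean=20.0,
        missing_rate=0.0,
        seed=seed,
    )
    cfg.update(overrides)
    return SimConfig(**cfg)


def _feature_ids(n: int, prefix: str) -> list:
    width = max(4, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def generate_dataset(config: SimConfig):
    """Simulate one dataset under ``config``.

    Returns
    -------
    proteins, metabolites : OmicsMatrix
        Raw-scale (linear) intensity matrices, one per layer.
    traits : pandas.DataFrame
        Samples as rows; ``strain`` plus any trait named in a module's
        ``trait_effects``.  Seizure traits are 0 in all control samples.
    truth : GroundTruth
        Planted assignments, hubs, trait coefficients and pathway names.

    Reproducible bit-for-bit for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = 2 * config.n_per_group
    group = np.repeat([0, 1], config.n_per_group)  # controls first
    samples = [f"control_{i + 1}" for i in range(config.n_per_group)] + [
        f"case_{i + 1}" for i in range(config.n_per_group)
    ]

    prot_ids = _feature_ids(config.n_proteins, "P")
    met_ids = _feature_ids(config.n_metabolites, "M")

    # latent factors, one per module
    z = {
        mod.name: mod.group_effect * group + rng.standard_normal(n)
        for mod in config.modules
    }

    log2 = pd.DataFrame(
        config.baseline_mean
        + config.noise_sd * rng.standard_normal((config.n_proteins + config.n_metabolites, n)),
        index=prot_ids + met_ids,
        columns=samples,
    )

    assignments: dict = {}
    hubs: dict = {}
    next_p, next_m = 0, 0
    for mod in config.modules:
        members = prot_ids[next_p : next_p + mod.size_proteins]
        next_p += mod.size_proteins
        members += met_ids[next_m : next_m + mod.size_metabolites]
        next_m += mod.size_metabolites
        loadings = np.full(len(members), mod.loading)
        loadings[0] = mod.hub_loading  # first member (a protein if any) is the hub
        hubs[mod.name] = members[0]
        for feat, a in zip(members, loadings):
            assignments[feat] = mod.name
            log2.loc[feat] += a * z[mod.name]

    raw = 2.0 ** log2
    proteins = make_matrix(raw.loc[prot_ids], PROTEIN)
    met_vals = raw.loc[met_ids].copy()
    if config.missing_rate > 0:
        mask = rng.random(met_vals.shape) < config.missing_rate
        met_vals = met_vals.mask(mask)
    metabolites = make_matrix(met_vals, METABOLITE)

    trait_names: list = []
    for mod in config.modules:
        for t in mod.trait_effects:
            if t not in trait_names:
                trait_names.append(t)
    traits = pd.DataFrame({"strain": group.astype(float)}, index=pd.Index(samples, name="sample"))
    seizure_traits = {"seizure_count", "mean_seizure_duration"}
    for t in trait_names:
        y = config.trait_noise_sd * rng.standard_normal(n)
        for mod in config.modules:
            coef = mod.trait_effects.get(t, 0.0)
            if coef:
                y = y + coef * z[mod.name]
        if t in seizure_traits:
            y = np.where(group == 0, 0.0, y)
        traits[t] = y

    truth = GroundTruth(
        assignments=assignments,
        hubs=hubs,
        trait_effects={m.name: dict(m.trait_effects) for m in config.modules},
        pathways={m.name: f"{m.name}_set" for m in config.modules},
        background=[f for f in prot_ids + met_ids if f not in assignments],
    )
    return proteins, metabolites, traits, truth


def generate_pathways(
    truth: GroundTruth,
    n_decoy_sets: int = 0,
    decoy_size: int = 10,
    seed: int = 0,
) -> dict:
    """Pathway sets for enrichment testing: one set per planted module equal
    to its member list, plus random decoy sets drawn from the background.

    Returns a mapping set name -> sorted member list, serializable as GMT.
    """
    if not truth.assignments:
        raise ValueError("ground truth has no planted modules")
    if n_decoy_sets > 0 and decoy_size > len(truth.background):
        raise ValueError(
            f"decoy_size {decoy_size} exceeds background size {len(truth.background)}"
        )
    rng = np.random.default_rng(seed)
    db: dict = {}
    for module in sorted(truth.pathways):
        db[truth.pathways[module]] = truth.members(module)
    for i in range(n_decoy_sets):
        picked = rng.choice(truth.background, size=decoy_size, replace=False)
        db[f"decoy_{i + 1:03d}"] = sorted(picked.tolist())
    return db
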
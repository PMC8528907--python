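"""Synthetic specialist/generalist communities and read-count sampling.

The generator encodes the community structure the diversity analysis is
meant to detect: many *specialist* taxa carrying small function repertoires
drawn mostly from a shared core pool, and a few *generalist* taxa carrying
large repertoires drawn mostly from a wide accessory pool.  A disturbance
acts as selection on repertoire size — taxa are re-weighted by
``exp(s * z)`` where z is the standardized repertoire size — so disturbed
communities concentrate onto generalists.  Taxonomic (OTU) tables are
multinomial reads over taxon abundances; functional (GO-term) tables are
multinomial reads over the induced marginal

    P(function g) = sum_i  abundance_i * [g in R_i] / |R_i|,

i.e., each read picks a taxon by abundance and then one of its functions
uniformly.  The designed-in signature is therefore lower taxonomic 2D and
higher functional 1D in the disturbed group.

All randomness flows from a single root seed; each sample gets the child
seed ``root + sample_index`` recorded in its metadata label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .tables import CountTable, SampleMetadata

__all__ = [
    "SimulationConfig",
    "TaxonProfile",
    "CommunityState",
    "generate_community",
    "apply_disturbance",
    "sample_taxonomic_reads",
    "sample_functional_reads",
    "generate_experiment",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for the synthetic disturbance experiment.

    Defaults describe the reference scenario: a taxon-rich community of 150
    narrow-repertoire specialists sharing a small core function pool, plus
    10 broad-repertoire generalists reaching into a large accessory pool,
    with moderate lognormal abundance heterogeneity and selection strength
    s = 2.5 under disturbance.
    """

    n_specialists: int = 150
    n_generalists: int = 10
    specialist_repertoire_range: tuple[int, int] = (40, 120)
    generalist_repertoire_range: tuple[int, int] = (400, 800)
    core_pool_size: int = 150
    accessory_pool_size: int = 5000
    specialist_core_fraction: float = 0.8
    generalist_core_fraction: float = 0.1
    abundance_lognormal_sigma: float = 1.0
    selection_strength: float = 2.5
    read_depth_taxonomic: int = 100_000
    read_depth_functional: int = 100_000
    n_replicates_per_group: int = 5
    seed: int = 42

    def __post_init__(self) -> None:
        pool = self.core_pool_size + self.accessory_pool_size
        for name, (lo, hi) in (
            ("specialist", self.specialist_repertoire_range),
            ("generalist", self.generalist_repertoire_range),
        ):
            if not 1 <= lo <= hi:
                raise ValueError(f"invalid {name} repertoire range ({lo}, {hi})")
            if hi > pool:
                raise ValueError(
                    f"{name} repertoire range upper bound {hi} exceeds the "
                    f"function pool size {pool}"
                )
        s_lo, s_hi = self.specialist_repertoire_range
        g_lo, g_hi = self.generalist_repertoire_range
        if (g_lo + g_hi) / 2 <= (s_lo + s_hi) / 2:
            raise ValueError(
                "generalist repertoires must be larger than specialist repertoires "
                "on average; adjust the repertoire ranges"
            )
        for name, frac in (
            ("specialist_core_fraction", self.specialist_core_fraction),
            ("generalist_core_fraction", self.generalist_core_fraction),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.read_depth_taxonomic < 1 or self.read_depth_functional < 1:
            raise ValueError("read depths must be >= 1")
        if self.selection_strength < 0:
            raise ValueError("selection strength must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TaxonProfile:
    taxon_id: str
    guild: str  # "specialist" | "generalist"
    repertoire: frozenset[str]

    @property
    def repertoire_size(self) -> int:
        return len(self.repertoire)


@dataclass(frozen=True)
class CommunityState:
    profiles: tuple[TaxonProfile, ...]
    abundances: np.ndarray  # sums to 1
    disturbed: bool = False

    def __post_init__(self) -> None:
        a = np.asarray(self.abundances, dtype=np.float64)
        if a.size != len(self.profiles):
            raise ValueError("abundance vector length must match profile count")
        if abs(a.sum() - 1.0) > 1e-9 or np.any(a < 0):
            raise ValueError("abundances must be non-negative and sum to 1")
        object.__setattr__(self, "abundances", a)

    @property
    def taxon_ids(self) -> list[str]:
        return [p.taxon_id for p in self.profiles]

    def guild_share(self, guild: str) -> float:
        mask = np.array([p.guild == guild for p in self.profiles])
        return float(self.abundances[mask].sum())


def _core_function_ids(config: SimulationConfig) -> list[str]:
    return [f"GO:C{k:05d}" for k in range(config.core_pool_size)]


def _accessory_function_ids(config: SimulationConfig) -> list[str]:
    return [f"GO:A{k:05d}" for k in range(config.accessory_pool_size)]


def _draw_repertoire(
    rng: np.random.Generator,
    size: int,
    core_fraction: float,
    core_ids: Sequence[str],
    accessory_ids: Sequence[str],
) -> frozenset[str]:
    n_core = int(round(core_fraction * size))
    n_core = min(n_core, len(core_ids))
    n_acc = size - n_core
    if n_acc > len(accessory_ids):
        raise ValueError(
            f"repertoire of size {size} needs {n_acc} accessory functions but the "
            f"accessory pool holds only {len(accessory_ids)}"
        )
    chosen = list(rng.choice(len(core_ids), size=n_core, replace=False))
    funcs = {core_ids[k] for k in chosen}
    chosen_acc = rng.choice(len(accessory_ids), size=n_acc, replace=False)
    funcs.update(accessory_ids[k] for k in chosen_acc)
    return frozenset(funcs)


def generate_community(
    config: SimulationConfig, seed: int | np.random.Generator
) -> CommunityState:
    """Draw one community: repertoires per guild, lognormal baseline abundances."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    core_ids = _core_function_ids(config)
    acc_ids = _accessory_function_ids(config)
    profiles: list[TaxonProfile] = []
    specs = [("specialist", config.n_specialists, config.specialist_repertoire_range,
              config.specialist_core_fraction),
             ("generalist", config.n_generalists, config.generalist_repertoire_range,
              config.generalist_core_fraction)]
    idx = 0
    for guild, count, (lo, hi), core_frac in specs:
        for _ in range(count):
            size = int(rng.integers(lo, hi + 1))
            rep = _draw_repertoire(rng, size, core_frac, core_ids, acc_ids)
            profiles.append(TaxonProfile(f"otu{idx:04d}", guild, rep))
            idx += 1
    raw = rng.lognormal(mean=0.0, sigma=config.abundance_lognormal_sigma,
                        size=len(profiles))
    return CommunityState(tuple(profiles), raw / raw.sum(), disturbed=False)


def apply_disturbance(state: CommunityState, s: float) -> CommunityState:
    """Re-weight abundances by selection on repertoire size.

        w_i  ∝  a_i * exp( s * (|R_i| - mean|R|) / sd|R| ),   renormalized,

    with sd the sample SD (n-1) of repertoire sizes.  s = 0 is the identity;
    for s > 0 the total generalist share strictly increases.
    """
    if s < 0:
        raise ValueError("selection strength must be >= 0")
    if s == 0:
        return CommunityState(state.profiles, state.abundances, disturbed=True)
    sizes = np.array([p.repertoire_size for p in state.profiles], dtype=np.float64)
    sd = sizes.std(ddof=1)
    if sd == 0:
        raise ValueError(
            "all repertoires have equal size; selection on repertoire size is undefined"
        )
    z = (sizes - sizes.mean()) / sd
    w = state.abundances * np.exp(s * z)
    return CommunityState(state.profiles, w / w.sum(), disturbed=True)


def sample_taxonomic_reads(
    state: CommunityState, depth: int, seed: int | np.random.Generator
) -> pd.Series:
    """Multinomial OTU read counts at the given depth (zeros retained)."""
    if depth < 1:
        raise ValueError("read depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = rng.multinomial(depth, state.abundances)
    return pd.Series(counts, index=state.taxon_ids, dtype=np.int64)


def functional_marginal(state: CommunityState) -> pd.Series:
    """Exact per-function read probability induced by the community."""
    probs: dict[str, float] = {}
    for profile, a in zip(state.profiles, state.abundances):
        if profile.repertoire_size == 0:
            raise ValueError(f"taxon {profile.taxon_id!r} has an empty repertoire")
        share = a / profile.repertoire_size
        for g in profile.repertoire:
            probs[g] = probs.get(g, 0.0) + share
    out = pd.Series(probs, dtype=np.float64).sort_index()
    return out / out.sum()


def sample_functional_reads(
    state: CommunityState, depth: int, seed: int | np.random.Generator
) -> pd.Series:
    """Multinomial GO-term read counts: taxon by abundance, then a uniform
    draw from its repertoire (sampled directly from the induced marginal)."""
    if depth < 1:
        raise ValueError("read depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    marginal = functional_marginal(state)
    counts = rng.multinomial(depth, marginal.to_numpy())
    return pd.Series(counts, index=marginal.index, dtype=np.int64)


def generate_experiment(
    config: SimulationConfig | None = None,
) -> tuple[CountTable, CountTable, list[SampleMetadata]]:
    """Simulate the full disturbed-vs-control design.

    Each replicate is an independent community (separate chambers, separate
    communities): controls keep their baseline abundances (s = 0), disturbed
    replicates are re-weighted with the configured selection strength.  Both
    assay tables share sample IDs; metadata carries group, assay and the
    child seed used for each sample.
    """
    if config is None:
        config = SimulationConfig()
    n_rep = config.n_replicates_per_group
    if n_rep < 1:
        raise ValueError("need at least one replicate per group")
    tax_cols: dict[str, pd.Series] = {}
    fun_cols: dict[str, pd.Series] = {}
    metadata: list[SampleMetadata] = []
    sample_index = 0
    for group, s in (("control", 0.0), ("disturbed", config.selection_strength)):
        for r in range(n_rep):
            child_seed = config.seed + sample_index
            rng = np.random.default_rng(child_seed)
            sid = f"{group[:4]}_{r + 1:02d}"
            state = generate_community(config, rng)
            state = apply_disturbance(state, s)
            tax_cols[sid] = sample_taxonomic_reads(state, config.read_depth_taxonomic, rng)
            fun_cols[sid] = sample_functional_reads(state, config.read_depth_functional, rng)
            for assay in ("taxonomic", "functional"):
                metadata.append(
                    SampleMetadata(sid, "disturbed" if group == "disturbed" else "control",
                                   assay, label=f"seed={child_seed}"))
            sample_index += 1
    tax_frame = pd.DataFrame(tax_cols).fillna(0).astype(np.int64)
    fun_frame = pd.DataFrame(fun_cols).fillna(0).astype(np.int64)
    fun_frame = fun_frame.sort_index()
    taxonomic = CountTable.from_frame(tax_frame)
    functional = CountTable.from_frame(fun_frame)
    return taxonomic, functional, metadata
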
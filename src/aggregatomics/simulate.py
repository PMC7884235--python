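"""Synthetic aggregate-scale soil community generator.

Soil microbial communities are spatially structured: aggregates of a few
milligrams act as "microbial villages" that each harbour a subset of the
total community.  A bulk soil sample homogenises many such microhabitats,
while a single aggregate (or a 1 mg sample) captures only a few.  This
module emulates that structure with a microhabitat-mixture model:

* a fixed pool of microhabitat profiles, each a lognormal composition over
  the soil taxon pool, with optional planted pairwise associations realised
  through shared (or mutually exclusive) enrichment of taxa across profiles;
* samples that mix ``mass_mg * microhabitats_per_mg`` profiles -- drawn with
  replacement for bulk soil, as one contiguous (spatially coherent) block
  for aggregates -- with Poisson copy-number noise;
* a reagent-contaminant pool, disjoint from the soil taxa, added to every
  extract at a fixed absolute load so that no-soil controls read out as
  nearly pure contaminant;
* multinomial read sampling at a lognormally varying depth.

Every draw is threaded through one :class:`numpy.random.Generator`, so a
``SimConfig`` plus seed reproduces the experiment byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .feature_table import SVTable

__all__ = [
    "MicrohabitatProfile",
    "PlantedAssociation",
    "SimConfig",
    "EXPERIMENT_DESIGNS",
    "aliquot_mass_for_equivalent",
    "build_microhabitat_profiles",
    "simulate_sample",
    "simulate_homogenate",
    "add_contamination",
    "sequence_sample",
    "generate_experiment",
    "simulate_null_table",
]


@dataclass(frozen=True)
class PlantedAssociation:
    """Ground-truth pairwise association planted into the microhabitat pool.

    ``sign=+1`` couples the enrichment pattern of the two taxa across
    microhabitats (co-presence); ``sign=-1`` makes them mutually exclusive.
    ``strength`` is the probability that the coupling is enforced in a
    given microhabitat (1.0 = deterministic).
    """

    taxon_a: str
    taxon_b: str
    sign: int = 1
    strength: float = 1.0

    def __post_init__(self) -> None:
        if self.taxon_a == self.taxon_b:
            raise ValueError("association endpoints must differ")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must lie in [0, 1]")


@dataclass(frozen=True)
class MicrohabitatProfile:
    """One microhabitat: a closed composition plus a carrying density.

    ``carrying_density`` is the expected number of 16S copies per mg of
    soil contributed by this microhabitat.  ``enriched_taxa`` records which
    association taxa are in their enriched state here (ground truth only).
    """

    profile_id: str
    taxon_props: np.ndarray
    carrying_density: float
    enriched_taxa: frozenset = frozenset()

    def __post_init__(self) -> None:
        props = np.asarray(self.taxon_props, dtype=float)
        if np.any(props < 0):
            raise ValueError("taxon_props must be nonnegative")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("taxon_props must sum to 1")
        if self.carrying_density <= 0:
            raise ValueError("carrying_density must be positive")
        object.__setattr__(self, "taxon_props", props)


@dataclass(frozen=True)
class SimConfig:
    """All tuning constants of the generator.

    Defaults are calibrated to reproduce the qualitative behaviour of a
    heterogeneous arable topsoil sampled at masses between 1 and 250 mg:
    small samples subsample few microhabitats and therefore diverge from
    one another, bulk samples average the heterogeneity away, and the
    fixed reagent-contaminant load dominates extracts with little soil.
    """

    n_taxa: int = 150
    n_microhabitats: int = 1024
    lognormal_sigma: float = 1.0
    microhabitats_per_mg: float = 4.0
    depth_mean: float = 20_000.0
    depth_dispersion: float = 0.2
    carrying_density: float = 1.0e5  # 16S copies per mg soil
    n_contaminant_taxa: int = 30
    contaminant_profile: Optional[np.ndarray] = None
    contaminant_copies_per_extract: float = 7.5e5
    associations: tuple = ()
    enrich_prob: float = 0.3
    enrich_segments: int = 12
    enrich_abundance: float = 0.6
    enrich_boost: float = 25.0
    aggregate_fraction: float = 0.5
    aggregate_mass_sd: float = 1.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 2 or self.n_microhabitats < 1:
            raise ValueError("need n_taxa >= 2 and n_microhabitats >= 1")
        if self.lognormal_sigma < 0 or self.microhabitats_per_mg <= 0:
            raise ValueError("dispersion/grain parameters out of range")
        if self.depth_mean < 1 or self.carrying_density <= 0:
            raise ValueError("depth_mean and carrying_density must be positive")
        object.__setattr__(self, "associations", tuple(self.associations))

    @property
    def soil_taxa(self) -> list:
        return [f"SV{i + 1}" for i in range(self.n_taxa)]

    @property
    def contaminant_taxa(self) -> list:
        return [f"CONT{i + 1}" for i in range(self.n_contaminant_taxa)]

    def resolve_contaminant_profile(self, rng: np.random.Generator) -> np.ndarray:
        """Contaminant composition: configured, or a lognormal draw."""
        if self.contaminant_profile is not None:
            prof = np.asarray(self.contaminant_profile, dtype=float)
            if prof.size != self.n_contaminant_taxa:
                raise ValueError("contaminant_profile length mismatch")
            return prof / prof.sum()
        w = rng.lognormal(mean=0.0, sigma=1.0, size=self.n_contaminant_taxa)
        return w / w.sum()


#: Sample-group layouts of the three in-silico experiments:
#: (group, soil mass or soil-equivalent mass in mg, number of samples).
EXPERIMENT_DESIGNS = {
    "experiment1": (
        ("soil", 250.0, 8),
        ("soil", 125.0, 8),
        ("soil", 25.0, 8),
        ("soil", 5.0, 8),
        ("soil", 1.0, 8),
        ("control", 0.0, 6),
    ),
    "experiment2": (
        ("soil", 250.0, 8),
        ("homogenate", 25.0, 8),
        ("homogenate", 5.0, 8),
        ("homogenate", 1.0, 8),
        ("control", 0.0, 6),
    ),
    "experiment3": (
        ("soil", 250.0, 35),
        ("aggregate", 5.3, 37),
        ("control", 0.0, 9),
    ),
}


def aliquot_mass_for_equivalent(
    target_soil_mg: float, total_soil_mg: float, total_suspension_mg: float
) -> float:
    """Suspension mass whose DNA content matches ``target_soil_mg`` of soil.

    A slurry of ``total_suspension_mg`` derived from ``total_soil_mg`` of
    soil is homogeneous, so the aliquot mass scales linearly.  Reported to
    0.1 mg, the resolution of an analytical balance.
    """
    if min(target_soil_mg, total_soil_mg, total_suspension_mg) <= 0:
        raise ValueError("all masses must be positive")
    if target_soil_mg > total_soil_mg:
        raise ValueError("target soil mass exceeds soil in the suspension")
    return round(target_soil_mg / total_soil_mg * total_suspension_mg, 1)


def _arc_indicator(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Spatially contiguous enrichment: arcs on the microhabitat ring.

    Soil properties vary smoothly at the millimetre scale, so a taxon's
    preferred patches cluster.  The indicator covers ``enrich_prob`` of
    the ring in ``enrich_segments`` arcs at random positions, which keeps
    whole aggregates (contiguous blocks) coherently enriched or not.
    """
    n = config.n_microhabitats
    ind = np.zeros(n, dtype=bool)
    seg = max(1, config.enrich_segments)
    length = max(1, round(config.enrich_prob * n / seg))
    for _ in range(seg):
        start = rng.integers(n)
        ind[(start + np.arange(length)) % n] = True
    return ind


def _enrichment_indicators(
    config: SimConfig, rng: np.random.Generator
) -> dict:
    """Per-taxon boolean enrichment vectors over microhabitats.

    Only taxa named in a planted association carry an indicator; all other
    taxa vary through the lognormal weights alone, so an association-free,
    zero-dispersion pool collapses to identical uniform profiles.
    """
    known = set(config.soil_taxa)
    indicators: dict = {}
    for assoc in config.associations:
        for t in (assoc.taxon_a, assoc.taxon_b):
            if t not in known:
                raise ValueError(f"association references unknown taxon {t!r}")
        if assoc.taxon_a not in indicators:
            indicators[assoc.taxon_a] = _arc_indicator(config, rng)
        ind_a = indicators[assoc.taxon_a]
        coupled = rng.random(config.n_microhabitats) < assoc.strength
        free = _arc_indicator(config, rng)
        target = ind_a if assoc.sign == 1 else ~ind_a
        indicators[assoc.taxon_b] = np.where(coupled, target, free)
    return indicators


def build_microhabitat_profiles(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> list:
    """Draw the pool of microhabitat profiles for one experiment.

    Each profile takes i.i.d. per-taxon lognormal weights (sigma =
    ``lognormal_sigma``) closed to sum 1; association taxa are rescaled
    according to their enrichment state, realising the planted
    co-presence/exclusion pattern.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    indicators = _enrichment_indicators(config, rng)
    taxa = config.soil_taxa
    taxon_index = {t: i for i, t in enumerate(taxa)}
    weights = rng.lognormal(
        mean=0.0, sigma=config.lognormal_sigma,
        size=(config.n_microhabitats, config.n_taxa),
    )
    # Association taxa are conditionally present, low-abundance members
    # (like real co-occurrence network hubs): weight ``enrich_abundance``
    # relative to a typical background taxon where enriched, and
    # ``enrich_boost``-fold lower where not.  Keeping them minor parts of
    # the composition prevents their on/off swings from dragging every
    # other taxon's relative abundance along through closure.
    for taxon, ind in indicators.items():
        j = taxon_index[taxon]
        scale = config.enrich_abundance
        weights[:, j] *= np.where(ind, scale, scale / config.enrich_boost)
    profiles = []
    for k in range(config.n_microhabitats):
        props = weights[k] / weights[k].sum()
        enriched = frozenset(t for t, ind in indicators.items() if ind[k])
        profiles.append(
            MicrohabitatProfile(
                profile_id=f"MH{k + 1}",
                taxon_props=props,
                carrying_density=config.carrying_density,
                enriched_taxa=enriched,
            )
        )
    return profiles


def simulate_sample(
    profiles: Sequence[MicrohabitatProfile],
    mass_mg: float,
    group: str,
    rng: np.random.Generator,
    config: SimConfig,
) -> np.ndarray:
    """Absolute 16S copy-number vector of one soil extract.

    A bulk ("soil") sample of ``mass_mg`` mixes ``mass_mg *
    microhabitats_per_mg`` profiles drawn with replacement.  An
    "aggregate" is a single spatially coherent unit, so it draws one
    contiguous block of ``aggregate_fraction`` as many profiles -- fewer,
    more correlated microhabitats, hence stronger community heterogeneity
    at equal mass.  Copy numbers get Poisson noise around the mass-weighted
    mixture expectation.
    """
    if mass_mg <= 0:
        raise ValueError("mass_mg must be positive")
    n_mix = max(1, round(mass_mg * config.microhabitats_per_mg))
    n_profiles = len(profiles)
    if group == "aggregate":
        n_mix = max(1, round(n_mix * config.aggregate_fraction))
        start = rng.integers(n_profiles)
        idx = (start + np.arange(n_mix)) % n_profiles
    else:
        idx = rng.integers(n_profiles, size=n_mix)
    lam = np.zeros(len(profiles[0].taxon_props))
    for i in idx:
        p = profiles[i]
        lam += p.taxon_props * p.carrying_density
    lam *= mass_mg / n_mix
    return rng.poisson(lam).astype(np.int64)


def simulate_homogenate(
    pool: np.ndarray,
    aliquot_masses: Sequence[float],
    total_mass: float,
    rng: np.random.Generator,
) -> list:
    """Binomially thin a pooled, vortexed extract into aliquots.

    ``pool`` is the element-wise sum of the contributing samples' copy
    vectors; each molecule lands in an aliquot of mass ``m`` with
    probability ``m / total_mass``, so all aliquots share one expected
    composition -- the homogenate-control logic.
    """
    pool = np.asarray(pool)
    out = []
    for m in aliquot_masses:
        if m > total_mass:
            raise ValueError("aliquot mass exceeds the pooled mass")
        p = m / total_mass
        out.append(rng.binomial(pool, p).astype(np.int64))
    return out


def add_contamination(
    copy_vector: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    contaminant_profile: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Append reagent-contaminant copies to an extract.

    The load is independent of soil mass (it comes from the kit), so a
    no-soil control reads out as nearly pure contaminant while a 250 mg
    extract carries only a few percent contaminant reads.  Returns a
    vector over soil taxa followed by contaminant taxa.
    """
    if contaminant_profile is None:
        contaminant_profile = config.resolve_contaminant_profile(rng)
    lam = config.contaminant_copies_per_extract * contaminant_profile
    contaminant = rng.poisson(lam).astype(np.int64)
    return np.concatenate([np.asarray(copy_vector, dtype=np.int64), contaminant])


def sequence_sample(
    copy_vector: np.ndarray, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial read sampling of an extract at a given depth."""
    copy_vector = np.asarray(copy_vector, dtype=float)
    total = copy_vector.sum()
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if total <= 0:
        raise ValueError("cannot sequence an all-zero extract")
    return rng.multinomial(int(depth), copy_vector / total)


def _draw_depth(config: SimConfig, rng: np.random.Generator) -> int:
    d = rng.lognormal(mean=math.log(config.depth_mean), sigma=config.depth_dispersion)
    return max(1, int(round(d)))


def generate_experiment(
    design: Sequence, config: SimConfig, seed: Optional[int] = None
):
    """Simulate one full experiment: table, metadata and truth ledger.

    ``design`` is a sequence of ``(group, mass_mg, n_samples)`` with group
    in {soil, aggregate, homogenate, control}; for homogenates ``mass_mg``
    is the soil-equivalent mass of the aliquot, thinned from a pooled
    slurry of two 250 mg extracts.  Returns ``(SVTable, metadata
    DataFrame, truth DataFrame)``; the truth ledger lists the planted
    associations for benchmarking network recovery.
    """
    design = list(design)
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    all_taxa = config.soil_taxa + config.contaminant_taxa
    if design and not all(
        g in ("soil", "aggregate", "homogenate", "control") for g, _, _ in design
    ):
        bad = [g for g, _, _ in design if g not in ("soil", "aggregate", "homogenate", "control")]
        raise ValueError(f"unknown sample group(s): {bad}")

    profiles = build_microhabitat_profiles(config, rng)
    contaminant_profile = config.resolve_contaminant_profile(rng)

    # Homogenate source: two 250 mg extracts pooled before aliquoting.
    pool = None
    pool_soil_mg = 2 * 250.0
    if any(g == "homogenate" for g, _, _ in design):
        pool = sum(
            simulate_sample(profiles, 250.0, "soil", rng, config) for _ in range(2)
        )

    columns, meta_rows = {}, []
    for group, mass, n_samples in design:
        for r in range(n_samples):
            sample_id = f"{group}_{mass:g}mg_r{r + 1}" if group != "control" else f"control_r{r + 1}"
            actual_mass = mass
            if group == "soil":
                soil = simulate_sample(profiles, mass, group, rng, config)
            elif group == "aggregate":
                actual_mass = max(0.5, rng.normal(mass, config.aggregate_mass_sd))
                soil = simulate_sample(profiles, actual_mass, group, rng, config)
            elif group == "homogenate":
                soil = simulate_homogenate(pool, [mass], pool_soil_mg, rng)[0]
            else:  # control: no soil at all
                soil = np.zeros(config.n_taxa, dtype=np.int64)
            extract = add_contamination(soil, config, rng, contaminant_profile)
            depth = _draw_depth(config, rng)
            reads = sequence_sample(extract, depth, rng)
            columns[sample_id] = reads
            meta_rows.append(
                {
                    "sample_id": sample_id,
                    "group": group,
                    "mass_mg": np.nan if group == "control" else round(actual_mass, 2),
                    "label": "control" if group == "control" else f"{group}_{mass:g}mg",
                    "experiment": "sim",
                    "is_control": group == "control",
                }
            )

    counts = pd.DataFrame(columns, index=all_taxa, dtype=np.int64)
    meta_cols = ["sample_id", "group", "mass_mg", "label", "experiment", "is_control"]
    metadata = pd.DataFrame(meta_rows, columns=meta_cols).set_index("sample_id")
    truth = pd.DataFrame(
        [
            {"taxon_a": a.taxon_a, "taxon_b": a.taxon_b, "sign": a.sign, "strength": a.strength}
            for a in config.associations
        ],
        columns=["taxon_a", "taxon_b", "sign", "strength"],
    )
    return SVTable(counts), metadata, truth


def generate_preset(preset: str, config: Optional[SimConfig] = None, seed: Optional[int] = None):
    """Run one of the three canned experiment layouts."""
    if preset not in EXPERIMENT_DESIGNS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(EXPERIMENT_DESIGNS)}")
    if config is None:
        config = SimConfig() if seed is None else SimConfig(seed=seed)
    elif seed is not None:
        config = replace(config, seed=seed)
    return generate_experiment(EXPERIMENT_DESIGNS[preset], config, seed=config.seed)


def simulate_null_table(
    n_taxa: int,
    n_samples: int,
    depth: int,
    seed: int,
    sigma_taxon: float = 1.0,
    sigma_sample: float = 1.0,
) -> SVTable:
    """Count table of mutually independent lognormal-abundance taxa.

    Per taxon a lognormal baseline, per sample-and-taxon an independent
    lognormal fluctuation, then multinomial reads -- the global null for
    network calibration, in which any inter-taxon correlation is purely
    compositional or sampling noise.
    """
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=0.0, sigma=sigma_taxon, size=n_taxa)
    w = base[:, None] * rng.lognormal(
        mean=0.0, sigma=sigma_sample, size=(n_taxa, n_samples)
    )
    counts = np.column_stack(
        [rng.multinomial(depth, w[:, j] / w[:, j].sum()) for j in range(n_samples)]
    )
    df = pd.DataFrame(
        counts,
        index=[f"SV{i + 1}" for i in range(n_taxa)],
        columns=[f"S{j + 1}" for j in range(n_samples)],
    )
    return SVTable(df)
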
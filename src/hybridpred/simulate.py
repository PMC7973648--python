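"""Synthetic hybrid-breeding data generator with known ground truth.

Emulates a factorial testcross programme: a panel of fully homozygous
pollinator lines structured into breeding pools, crossed to a small set of
male-sterile testers, with parental transcript and metabolite layers
downstream of the genotypes, and hybrid traits of mixed
additive/dominance/epistatic architecture observed in multi-location,
multi-trial field designs.

Pool structure follows a Balding-Nichols model: each pool's allele
frequency at a SNP is a Beta draw around a shared ancestral frequency with
differentiation parameter ``fst``, so the expected squared frequency
divergence between two pools is ``2 * fst * p0 * (1 - p0)``.

Traits are built from explicit per-SNP additive and dominance effects and
pairwise additive x additive interactions; each architecture component is
rescaled so its realized variance fraction matches the configured target,
and the plant-level residual SD is calibrated empirically so that the
replicate-corrected broad-sense heritability
``H2 = s2_G / (s2_G + s2_e / n_reps)`` hits the configured value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CrossPlan, OmicsMatrix
from .hybrids import make_hybrid_profiles


@dataclass
class SimulationConfig:
    """Parameters of the synthetic breeding programme.

    Counts default to a desk-scale population (300 pollinators, 2 testers,
    2,000 SNPs, 1,000 transcripts, 150 metabolites); the full-scale layout
    (475 pollinators, 13k SNPs, 19k transcripts) is reachable by raising
    them.
    """

    n_pollinators: int = 300
    n_testers: int = 2
    n_pools: int = 3
    n_snp: int = 2000
    n_transcript: int = 1000
    n_metabolite: int = 150
    h2: float = 0.7
    var_frac_add: float = 0.7
    var_frac_dom: float = 0.2
    var_frac_epi: float = 0.1
    trait_mean: float = 30.0  # baseline, units of the trait (genetic SD = 1)
    n_locations: int = 3
    n_trials: int = 2
    n_reps: int = 4          # plant replicates per genotype (the n0 of H2)
    fst: float = 0.15        # Balding-Nichols pool differentiation
    n_causal: int = 200      # causal SNPs per additive/dominance component
    n_epi_pairs: int = 100
    # endophenotype layer coupling (tpm-like scale)
    cis_effect_sd: float = 3.0
    pool_effect_sd: float = 2.0
    transcript_noise_sd: float = 2.0
    metabolite_noise_sd: float = 1.0
    # nuisance variances of the trial design (trait units; genetic SD = 1)
    trial_effect_sd: float = 0.3
    location_effect_sd: float = 0.5
    trial_location_sd: float = 0.2
    loc_genotype_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.var_frac_add, self.var_frac_dom, self.var_frac_epi)
        if any(f < 0 for f in fracs):
            raise ValueError("variance fractions must be nonnegative")
        if abs(sum(fracs) - 1.0) > 1e-8:
            raise ValueError(f"variance fractions must sum to 1, got {sum(fracs)}")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        for name in ("n_pollinators", "n_testers", "n_pools", "n_snp", "n_transcript",
                     "n_metabolite", "n_locations", "n_trials", "n_reps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_snp < 2 or self.n_pollinators < 2:
            raise ValueError("need n_snp >= 2 and n_pollinators >= 2")


@dataclass
class ParentPopulation:
    """Simulated parental panel: genotypes, pool labels and the frequencies
    that generated them (kept for parameter-recovery checks)."""

    genotypes: OmicsMatrix          # parents x SNPs, dosages 0/2
    pools: pd.Series                # pool label per parent id
    ancestral_freq: np.ndarray      # per-SNP ancestral allele frequency
    pool_freq: pd.DataFrame         # pools x SNPs allele frequencies


@dataclass
class GroundTruth:
    """True genetic architecture behind a simulated trait."""

    additive_effects: np.ndarray        # per SNP (0 outside causal set)
    dominance_effects: np.ndarray
    epistatic_pairs: list[tuple[int, int, float]]
    genetic_values: pd.Series           # per hybrid
    component_values: dict[str, np.ndarray]  # centred add/dom/epi parts
    sigma2_g: float                     # realized var of genetic values
    sigma2_e: float                     # calibrated plant-level residual
    pools: pd.Series | None = None
    dosage_center: np.ndarray | None = None  # column means used for epistasis
    trait_mean: float = 0.0
    value_offset: float = 0.0  # constant subtracted when centring components

    def realized_fractions(self) -> dict[str, float]:
        total = sum(np.var(v) for v in self.component_values.values())
        return {k: float(np.var(v) / total) for k, v in self.component_values.items()}


def _polymorphize(geno: np.ndarray, rng: np.random.Generator) -> int:
    """Flip one random individual at panel-monomorphic SNPs; returns count."""
    freq = geno.mean(axis=0) / 2.0
    mono = np.flatnonzero((freq == 0.0) | (freq == 1.0))
    for j in mono:
        i = rng.integers(geno.shape[0])
        geno[i, j] = 2 - geno[i, j]
    return mono.size


def simulate_parents(config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> ParentPopulation:
    """Draw fully homozygous parents (dosage 0/2) with pool structure.

    Pollinators are split evenly over ``n_pools`` Balding-Nichols pools;
    testers form an extra pool of their own. Panel-monomorphic SNPs are
    repaired by flipping a single random individual so every SNP is
    polymorphic across the panel.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p0 = rng.uniform(0.1, 0.9, size=config.n_snp)
    n_groups = config.n_pools + 1  # + tester pool
    if config.fst > 0:
        a = p0 * (1 - config.fst) / config.fst
        b = (1 - p0) * (1 - config.fst) / config.fst
        pool_freq = rng.beta(a, b, size=(n_groups, config.n_snp))
    else:
        pool_freq = np.tile(p0, (n_groups, 1))
    pool_freq = np.clip(pool_freq, 1e-4, 1 - 1e-4)

    pool_names = [f"pool{k + 1}" for k in range(config.n_pools)] + ["tester"]
    pol_ids = [f"P{i + 1:04d}" for i in range(config.n_pollinators)]
    tester_ids = [f"MS{j + 1}" for j in range(config.n_testers)]
    pol_pool = np.arange(config.n_pollinators) % config.n_pools

    rows = np.empty((config.n_pollinators + config.n_testers, config.n_snp), dtype=float)
    for i, k in enumerate(pol_pool):
        rows[i] = 2.0 * (rng.random(config.n_snp) < pool_freq[k])
    for j in range(config.n_testers):
        rows[config.n_pollinators + j] = 2.0 * (rng.random(config.n_snp) < pool_freq[-1])
    _polymorphize(rows, rng)

    ids = pol_ids + tester_ids
    labels = [pool_names[k] for k in pol_pool] + ["tester"] * config.n_testers
    snp_ids = [f"snp{j + 1:05d}" for j in range(config.n_snp)]
    geno = OmicsMatrix(pd.DataFrame(rows, index=ids, columns=snp_ids), "genomic")
    pools = pd.Series(labels, index=ids, name="pool")
    freq_df = pd.DataFrame(pool_freq, index=pool_names, columns=snp_ids)
    return ParentPopulation(geno, pools, p0, freq_df)


def simulate_endophenotypes(
    parents: ParentPopulation,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[OmicsMatrix, OmicsMatrix]:
    """Simulate parental transcript and metabolite layers.

    Each transcript is baseline + a cis effect of one randomly assigned SNP
    + a trans pool effect + noise, clipped to a nonnegative tpm-like scale.
    Each metabolite is a sparse linear combination of three transcripts +
    noise, so the metabolome sits downstream of the transcriptome which
    itself carries genomic and pool information.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    G = parents.genotypes.values
    n_ind = G.shape[0]
    pool_codes = pd.Categorical(parents.pools).codes

    cis_snp = rng.integers(config.n_snp, size=config.n_transcript)
    baseline = rng.lognormal(mean=np.log(20.0), sigma=0.8, size=config.n_transcript)
    beta_cis = rng.normal(0.0, config.cis_effect_sd, size=config.n_transcript)
    n_pools = pool_codes.max() + 1
    delta_pool = rng.normal(0.0, config.pool_effect_sd, size=(n_pools, config.n_transcript))

    T = (baseline[None, :]
         + beta_cis[None, :] * G[:, cis_snp]
         + delta_pool[pool_codes, :]
         + rng.normal(0.0, config.transcript_noise_sd, size=(n_ind, config.n_transcript)))
    T = np.maximum(T, 0.0)

    parent_tx = rng.integers(config.n_transcript, size=(config.n_metabolite, 3))
    weights = rng.normal(0.0, 1.0, size=(config.n_metabolite, 3)) / np.sqrt(3)
    m_base = rng.lognormal(mean=np.log(10.0), sigma=0.5, size=config.n_metabolite)
    # scale transcript inputs so metabolite variance is O(1) regardless of tpm scale
    T_std = (T - T.mean(axis=0)) / np.where(T.std(axis=0) > 0, T.std(axis=0), 1.0)
    M = (m_base[None, :]
         + np.einsum("ikj,kj->ik", T_std[:, parent_tx], weights)
         + rng.normal(0.0, config.metabolite_noise_sd, size=(n_ind, config.n_metabolite)))
    M = np.maximum(M, 0.0)

    ids = parents.genotypes.individuals
    tx_ids = [f"tx{j + 1:05d}" for j in range(config.n_transcript)]
    mb_ids = [f"met{j + 1:04d}" for j in range(config.n_metabolite)]
    tx = OmicsMatrix(pd.DataFrame(T, index=ids, columns=tx_ids), "transcriptomic")
    tx.data.attrs["cis_snp"] = cis_snp.tolist()
    mb = OmicsMatrix(pd.DataFrame(M, index=ids, columns=mb_ids), "metabolic")
    return tx, mb


def _architecture(hybrid_geno: np.ndarray, config: SimulationConfig,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray,
                                                     list[tuple[int, int, float]],
                                                     dict[str, np.ndarray]]:
    """Draw causal effects and return centred, fraction-scaled components."""
    n_snp = hybrid_geno.shape[1]
    n_causal = min(config.n_causal, n_snp)
    het = (hybrid_geno == 1.0).astype(float)
    Xc = hybrid_geno - hybrid_geno.mean(axis=0)

    a = np.zeros(n_snp)
    d = np.zeros(n_snp)
    idx_a = rng.choice(n_snp, size=n_causal, replace=False)
    idx_d = rng.choice(n_snp, size=n_causal, replace=False)
    a[idx_a] = rng.normal(size=n_causal)
    d[idx_d] = rng.normal(size=n_causal)

    pairs: list[tuple[int, int, float]] = []
    n_pairs = min(config.n_epi_pairs, n_snp * (n_snp - 1) // 2)
    seen: set[tuple[int, int]] = set()
    while len(pairs) < n_pairs:
        j, k = rng.choice(n_snp, size=2, replace=False)
        key = (min(j, k), max(j, k))
        if key in seen:
            continue
        seen.add(key)
        pairs.append((key[0], key[1], float(rng.normal())))

    comp = {
        "additive": hybrid_geno @ a,
        "dominance": het @ d,
        "epistatic": sum(e * Xc[:, j] * Xc[:, k] for j, k, e in pairs),
    }
    targets = {"additive": config.var_frac_add, "dominance": config.var_frac_dom,
               "epistatic": config.var_frac_epi}
    scaled = {}
    scale_of = {"additive": 0.0, "dominance": 0.0, "epistatic": 0.0}
    offset = 0.0
    for name, v in comp.items():
        v = np.asarray(v, dtype=float)
        sd = (v - v.mean()).std()
        target_sd = np.sqrt(targets[name])
        s = target_sd / sd if sd > 0 and target_sd > 0 else 0.0
        scale_of[name] = s
        offset += v.mean() * s
        scaled[name] = (v - v.mean()) * s
    a *= scale_of["additive"]
    d *= scale_of["dominance"]
    pairs = [(j, k, e * scale_of["epistatic"]) for j, k, e in pairs]
    return a, d, pairs, scaled, offset


def simulate_trait(
    hybrids: OmicsMatrix,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    pools: pd.Series | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a trait on hybrid genotypes and its multi-trial observations.

    Returns a long phenotype table (genotype, trial, location, replicate,
    value) plus the generating :class:`GroundTruth`. Observations follow
    ``y = g + T + L + TxL + LxG + e`` with plant-level residual SD
    calibrated so the replicate-corrected heritability equals ``config.h2``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    if config.h2 == 1.0 and config.n_reps == 0:
        raise ValueError("h2 = 1 requires at least one replicate")
    geno = hybrids.values
    a, d, pairs, comps, offset = _architecture(geno, config, rng)
    g = comps["additive"] + comps["dominance"] + comps["epistatic"]
    ids = hybrids.individuals
    gvals = pd.Series(g, index=ids, name="genetic_value")

    sigma2_g = float(np.var(g))
    if config.h2 > 0:
        sigma2_e = sigma2_g * config.n_reps * (1.0 - config.h2) / config.h2
    else:
        sigma2_e = 1.0 if sigma2_g == 0 else sigma2_g * config.n_reps * 100.0

    n_h = len(ids)
    trials = [f"T{t + 1}" for t in range(config.n_trials)]
    locs = [f"L{l + 1}" for l in range(config.n_locations)]
    t_eff = rng.normal(0.0, config.trial_effect_sd, size=config.n_trials)
    l_eff = rng.normal(0.0, config.location_effect_sd, size=config.n_locations)
    tl_eff = rng.normal(0.0, config.trial_location_sd,
                        size=(config.n_trials, config.n_locations))
    lg_eff = rng.normal(0.0, config.loc_genotype_sd, size=(config.n_locations, n_h))

    records = []
    sd_e = np.sqrt(sigma2_e)
    for t in range(config.n_trials):
        for l in range(config.n_locations):
            for r in range(config.n_reps):
                eps = rng.normal(0.0, sd_e, size=n_h)
                vals = (config.trait_mean + g + t_eff[t] + l_eff[l]
                        + tl_eff[t, l] + lg_eff[l] + eps)
                records.append(pd.DataFrame({
                    "genotype": ids, "trial": trials[t], "location": locs[l],
                    "replicate": r + 1, "value": vals,
                }))
    pheno = pd.concat(records, ignore_index=True)
    truth = GroundTruth(a, d, pairs, gvals, comps, sigma2_g, sigma2_e, pools,
                        dosage_center=geno.mean(axis=0),
                        trait_mean=config.trait_mean, value_offset=offset)
    return pheno, truth


def evaluate_genetic_values(truth: GroundTruth, geno: OmicsMatrix) -> pd.Series:
    """Evaluate the ground-truth architecture on any dosage matrix (e.g. the
    parents), on the same scale as the hybrid genetic values."""
    X = geno.values
    Xc = X - truth.dosage_center
    g = X @ truth.additive_effects + (X == 1.0).astype(float) @ truth.dominance_effects
    for j, k, e in truth.epistatic_pairs:
        g = g + e * Xc[:, j] * Xc[:, k]
    return pd.Series(g - truth.value_offset, index=geno.individuals,
                     name="genetic_value")


@dataclass
class SyntheticDataset:
    """Bundle of one full synthetic run: parents, hybrids, all layers, trait."""

    config: SimulationConfig
    parents: ParentPopulation
    plan: CrossPlan
    hybrid_genotypes: OmicsMatrix
    parent_transcriptome: OmicsMatrix
    parent_metabolome: OmicsMatrix
    phenotypes: pd.DataFrame
    truth: GroundTruth
    hybrid_means: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.hybrid_means = (
            self.phenotypes.groupby("genotype", sort=False)["value"].mean()
            .reindex(self.hybrid_genotypes.individuals)
        )


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run the full generator: parents -> endophenotypes -> hybrids -> trait.

    All randomness derives from ``config.seed`` via named child streams, so
    repeated calls are bit-identical.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_parents, rng_endo, rng_trait = (np.random.default_rng(c) for c in ss.spawn(3))
    parents = simulate_parents(config, rng_parents)
    tx, mb = simulate_endophenotypes(parents, config, rng_endo)
    pol_ids = [i for i in parents.genotypes.individuals if parents.pools[i] != "tester"]
    tester_ids = [i for i in parents.genotypes.individuals if parents.pools[i] == "tester"]
    plan = CrossPlan.factorial(pol_ids, tester_ids)
    hyb = make_hybrid_profiles(parents.genotypes, plan).profiles["genomic"]
    pheno, truth = simulate_trait(hyb, config, rng_trait, pools=parents.pools)
    return SyntheticDataset(config, parents, plan, hyb, tx, mb, pheno, truth)
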
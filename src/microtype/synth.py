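"""Synthetic multi-omics cohort generator.

Plants, with known ground truth, the statistical structure the analysis
stages assume: four community clusters realized through block-wise genus
multipliers, five genus co-abundance blocks driven by per-block latent
factors, NW/OB labels at fixed per-cluster probabilities, behavior scores
linearly tied to ordination axis 2, three dietary archetypes, cluster-
patterned lipid panels, and cluster-specific expression multipliers on a
species-stratified pathway table.

Expression "targets" are specified as the desired cluster-over-cohort
ratio of a feature's RNA:DNA level; the generator solves for the raw
per-cluster multipliers so that the sample-weighted cohort mean equals the
baseline, making a planted target of 4 recoverable as log2 = 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

from .core import FeatureTable, PairedOmicsTable, SampleMetadata, ValidationError

BLOCK_NAMES = ("Bifidobacterium", "Ruminococcus", "Dorea", "Prevotella", "Bacteroides")
CLUSTERS = ("C1", "C2", "C3", "C4")

#: per-cluster multiplier applied to each genus block's abundance (linear scale)
DEFAULT_BLOCK_MULTIPLIERS: dict[str, dict[str, float]] = {
    "C1": {},
    "C2": {"Bifidobacterium": 0.02},
    "C3": {"Bifidobacterium": 0.02, "Prevotella": 2.0, "Ruminococcus": 2.0},
    "C4": {"Bacteroides": 0.02, "Bifidobacterium": 3.0},
}

#: block-representative species used for the species-stratified omics tables
BLOCK_SPECIES = {
    "Bifidobacterium": "Bifidobacterium_longum",
    "Ruminococcus": "Ruminococcus_bromii",
    "Dorea": "Dorea_longicatena",
    "Prevotella": "Prevotella_copri",
    "Bacteroides": "Bacteroides_uniformis",
}
EXTRA_SPECIES = ("Escherichia_coli",)

DEFAULT_PATHWAYS = (
    "ko00010", "ko00020", "ko00500", "ko00052",
    "ko00250", "ko00260", "ko00330",
    "ko00100", "ko00120", "ko00121", "ko00561",
    "ko00627", "ko00930",
)
DEFAULT_KOS = (
    "K01442", "K00076", "K07007", "K03778", "K00170",
    "K00172", "K01667", "K01046", "K01995", "K01580",
)

#: (species, feature) -> cluster -> target over-abundance ratio vs cohort mean
DEFAULT_EXPRESSION_TARGETS: dict[tuple[str, str], dict[str, float]] = {
    ("Escherichia_coli", "K00076"): {"C2": 0.0, "C3": 0.0, "C4": 0.0},
    ("Ruminococcus_bromii", "ko00121"): {"C3": 2.0, "C4": 2.0},
    ("Ruminococcus_bromii", "K01442"): {"C3": 2.0, "C4": 2.0},
    ("Prevotella_copri", "ko00010"): {"C4": 4.0},
    ("Bacteroides_uniformis", "K07007"): {"C2": 2.0},
}

#: lipid -> cluster multipliers on the log-normal median
DEFAULT_LIPID_EFFECTS: dict[str, dict[str, float]] = {
    "acetate": {"C1": 2.0, "C2": 2.0},
    "propionate": {"C1": 2.0, "C2": 2.0},
    "butyrate": {"C1": 2.0, "C2": 2.0},
    "coprostanol": {"C3": 2.5, "C4": 2.5},
    "sitostanol_5b": {"C3": 4.0, "C4": 4.0},
    "campestanol_5b": {"C3": 2.5, "C4": 2.5},
    "cholesterol": {"C2": 2.0},
    "cholic_acid": {"C2": 2.5},
    "chenodeoxycholic_acid": {"C2": 2.5},
    "deoxycholic_acid": {"C4": 2.5},
    "lithocholic_acid": {"C4": 2.5},
    "ursodeoxycholic_acid": {},
    "sitosterol": {},
    "campesterol": {},
}

FOOD_ITEMS = (
    "bread", "pasta", "rice", "potatoes", "sweets", "fruit", "vegetables",
    "legumes", "red_meat", "white_meat", "fish", "eggs", "cheese", "milk",
    "yogurt", "olive_oil", "butter", "nuts", "wine", "soft_drinks",
)


@dataclass
class SynthConfig:
    """Study conditions for the synthetic cohort (all fields overridable)."""

    n_samples: int = 100
    cluster_proportions: tuple = (0.31, 0.33, 0.22, 0.14)
    nw_probability_per_cluster: tuple = (0.48, 0.28, 0.36, 0.36)
    n_genera: int = 40
    otus_per_genus: tuple = (3, 10)
    block_multipliers: dict = field(default_factory=lambda: {
        c: dict(v) for c, v in DEFAULT_BLOCK_MULTIPLIERS.items()
    })
    latent_loading: float = 0.15
    genus_noise_sd: float = 0.2
    genus_base_sd: float = 0.4
    cluster_profile_sd: float = 0.25
    block_profile_sd: float = 0.8
    block_mean_offsets: dict = field(default_factory=lambda: {
        "Bifidobacterium": 0.0, "Bacteroides": -0.4,
    })
    # within-sample concentration exponent (> 1 lowers evenness, hence
    # Shannon) planting the diversity ordering C1 ~ C3 > C2 ~ C4; the
    # transform is monotone per sample so rank-based stages are untouched
    evenness_exponents: dict = field(default_factory=lambda: {"C2": 1.25, "C4": 1.25})
    depth: int = 5000
    # behavior scores = intercept + slope * PCo2 + age_coef * age + noise
    ue_intercept: float = 17.0
    ue_slope: float = -60.0
    bite_intercept: float = 6.5
    bite_slope: float = -50.0
    behavior_age_coef: float = 0.05
    behavior_noise_sd: float = 0.5
    yfas_rate_per_cluster: tuple = (1.2, 2.2, 2.2, 3.2)
    lipid_effects: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_LIPID_EFFECTS.items()
    })
    lipid_noise_sd: float = 0.3
    diet_archetype_probs: tuple = (0.40, 0.35, 0.25)
    ffq_concentration: float = 150.0
    ffq_portions: float = 120.0
    expression_targets: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_EXPRESSION_TARGETS.items()
    })
    expression_noise_sd: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.cluster_proportions) - 1.0) > 1e-9:
            raise ValidationError("cluster_proportions must sum to 1")
        if self.depth < 1000:
            raise ValidationError("sequencing depth must be >= 1000")
        for cl, mult in self.block_multipliers.items():
            if any(m < 0 for m in mult.values()):
                raise ValidationError(f"negative block multiplier in {cl}")


@dataclass
class GroundTruth:
    cluster: pd.Series                    # sample -> C1..C4
    diet_archetype: pd.Series | None = None
    genus_block: dict[str, str] | None = None
    otu_genus: dict[str, str] | None = None
    behavior_slopes: dict[str, float] | None = None
    expression_multipliers: dict | None = None   # (species, feature) -> {cluster: E}
    pco2: pd.Series | None = None


def _block_profiles() -> np.ndarray:
    """5 block response profiles over 4 clusters.

    Rows are zero-mean across clusters with equal variance, and pairwise
    correlation exactly +-1/sqrt(5): five of the six icosahedral
    equiangular lines in the 3-dimensional centered subspace of R^4 (the
    optimum for five directions), so no two blocks share a response
    pattern.
    """
    phi = (1 + np.sqrt(5.0)) / 2.0
    lines = np.array([
        [0.0, 1.0, phi],
        [0.0, 1.0, -phi],
        [1.0, phi, 0.0],
        [1.0, -phi, 0.0],
        [phi, 0.0, 1.0],
    ])
    lines /= np.linalg.norm(lines, axis=1, keepdims=True)
    # orthonormal basis of the zero-mean subspace of R^4 (Helmert rows)
    h = np.zeros((3, 4))
    for i in range(1, 4):
        h[i - 1, :i] = 1.0
        h[i - 1, i] = -i
        h[i - 1] /= np.linalg.norm(h[i - 1])
    prof = lines @ h                     # 5 x 4, rows zero-mean, norm 1
    prof /= prof.std(axis=1, keepdims=True)
    # row order chosen so each block's response reinforces (never fights)
    # its planted multiplier pattern: Bifidobacterium peaks in C4 (where its
    # block is boosted), Prevotella in C3 (over-represented there), etc.
    return prof[[1, 4, 0, 3, 2]]


_BLOCK_PROFILES = _block_profiles()

# ---------------------------------------------------------------------------
# community structure
# ---------------------------------------------------------------------------

def _genus_names(config: SynthConfig) -> tuple[list[str], dict[str, str]]:
    """40 genus ids in 5 equal blocks; first genus of each block is canonical."""
    per_block = config.n_genera // len(BLOCK_NAMES)
    names, block_of = [], {}
    for b, block in enumerate(BLOCK_NAMES):
        for j in range(per_block + (1 if b < config.n_genera % len(BLOCK_NAMES) else 0)):
            name = block if j == 0 else f"{block}_rel{j}"
            names.append(name)
            block_of[name] = block
    return names, block_of


def _random_topology(names: list[str], rng: np.random.Generator, rate: float) -> str:
    """Random bifurcating newick subtree over ``names`` with Exp(1/rate) lengths."""
    if len(names) == 1:
        return f"{names[0]}:{rng.exponential(rate):.6f}"
    k = int(rng.integers(1, len(names)))
    left = _random_topology(names[:k], rng, rate)
    right = _random_topology(names[k:], rng, rate)
    return f"({left},{right}):{rng.exponential(rate):.6f}"


def simulate_tree(config: SynthConfig) -> tuple[skbio.TreeNode, dict[str, str]]:
    """Rooted tree: genus backbone with per-genus OTU subtrees grafted on.

    Returns the tree and the OTU -> genus map.  Deterministic for a seed:
    the same derived RNG stream also fixes the per-genus OTU counts used by
    the abundance stage.
    """
    rng = np.random.default_rng(config.rng_seed)
    genera, _ = _genus_names(config)
    otu_genus: dict[str, str] = {}
    subtrees = []
    counter = 1
    for g in genera:
        n_otus = int(rng.integers(config.otus_per_genus[0], config.otus_per_genus[1] + 1))
        otus = [f"OTU_{counter + i:04d}" for i in range(n_otus)]
        counter += n_otus
        for o in otus:
            otu_genus[o] = g
        subtrees.append(_random_topology(otus, rng, rate=0.05))
    shuffled = list(range(len(subtrees)))

    def backbone(idx: list[int]) -> str:
        if len(idx) == 1:
            return subtrees[idx[0]]
        k = int(rng.integers(1, len(idx)))
        return f"({backbone(idx[:k])},{backbone(idx[k:])}):{rng.exponential(0.5):.6f}"

    newick = f"({backbone(shuffled)});"
    tree = skbio.TreeNode.read([newick], convert_underscores=False)
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
    return tree, otu_genus


def simulate_abundances(
    config: SynthConfig, otu_genus: dict[str, str] | None = None
) -> tuple[FeatureTable, GroundTruth]:
    """OTU count table with planted clusters and co-abundance blocks.

    Genus abundance for sample s in cluster c:
    ``M_{c,b(g)} * exp(mu_g + lambda * f_{b,s} + eps)`` with one latent
    factor f per block per sample (positive within-block co-abundance).
    Genus mass is split over its OTUs by a fixed Dirichlet draw; counts by
    multinomial at the configured depth.
    """
    rng = np.random.default_rng(config.rng_seed)
    genera, block_of = _genus_names(config)
    if otu_genus is None:
        _, otu_genus = simulate_tree(config)
    otus = list(otu_genus)
    genus_otus = {g: [o for o in otus if otu_genus[o] == g] for g in genera}

    # structural draws (fixed per seed)
    struct = np.random.default_rng(config.rng_seed + 1)
    mu = {g: struct.normal(0.0, config.genus_base_sd)
          + (1.8 if g in BLOCK_NAMES else 0.0)
          + config.block_mean_offsets.get(block_of[g], 0.0)
          for g in genera}
    # each steady state is a distinct community profile, not just a
    # block-shifted copy of C1: per-genus cluster fingerprints plus a
    # deterministic per-block cluster response (equiangular profiles, so
    # no two blocks share a response pattern).
    delta = {(g, c): struct.normal(0.0, config.cluster_profile_sd)
             for g in genera for c in CLUSTERS}
    eta = {(b, c): config.block_profile_sd * _BLOCK_PROFILES[bi, ci]
           for bi, b in enumerate(BLOCK_NAMES) for ci, c in enumerate(CLUSTERS)}
    otu_split = {g: struct.dirichlet(np.full(len(genus_otus[g]), 2.0)) for g in genera}

    n = config.n_samples
    k = len(CLUSTERS)
    counts_per_cluster = np.floor(np.asarray(config.cluster_proportions) * n).astype(int)
    counts_per_cluster[0] += n - counts_per_cluster.sum()
    cluster_labels = np.repeat(CLUSTERS, counts_per_cluster)
    samples = [f"S{i + 1:03d}" for i in range(n)]

    lam, sd = config.latent_loading, config.genus_noise_sd
    depth = config.depth
    mat = np.zeros((n, len(otus)))
    otu_index = {o: i for i, o in enumerate(otus)}
    for s_idx, (sample, cl) in enumerate(zip(samples, cluster_labels)):
        factors = {b: rng.normal() for b in BLOCK_NAMES}
        mult = config.block_multipliers.get(cl, {})
        mass = np.zeros(len(otus))
        for g in genera:
            b = block_of[g]
            m = mult.get(b, 1.0)
            abund = m * np.exp(mu[g] + delta[(g, cl)] + eta[(b, cl)]
                               + lam * factors[b] + rng.normal(0.0, sd))
            for o, w in zip(genus_otus[g], otu_split[g]):
                mass[otu_index[o]] = abund * w
        gamma = config.evenness_exponents.get(cl, 1.0)
        if gamma != 1.0:
            mass = np.where(mass > 0, mass ** gamma, 0.0)
        probs = mass / mass.sum()
        mat[s_idx] = rng.multinomial(depth, probs)

    if any((mat[cluster_labels == cl] > 0).mean() < 0.01 for cl in CLUSTERS):
        import logging

        logging.getLogger("microtype").warning(
            "depth %d too low to realize the planted prevalence structure", depth
        )
    taxonomy = {o: f"k__Bacteria; g__{otu_genus[o]}" for o in otus}
    table = FeatureTable(pd.DataFrame(mat, index=samples, columns=otus),
                         level="otu", taxonomy=taxonomy)
    truth = GroundTruth(
        cluster=pd.Series(cluster_labels, index=samples, name="cluster"),
        genus_block=dict(block_of),
        otu_genus=dict(otu_genus),
    )
    return table, truth


def genus_table(otu_table: FeatureTable, otu_genus: dict[str, str]) -> FeatureTable:
    """Collapse OTU counts to genus level using the OTU -> genus map."""
    groups: dict[str, list[str]] = {}
    for o, g in otu_genus.items():
        groups.setdefault(g, []).append(o)
    data = {g: otu_table.data[cols].sum(axis=1) for g, cols in groups.items()}
    return FeatureTable(pd.DataFrame(data, index=otu_table.sample_ids), level="genus")


# ---------------------------------------------------------------------------
# host metadata
# ---------------------------------------------------------------------------

def simulate_metadata(
    config: SynthConfig,
    truth: GroundTruth,
    pco2: pd.Series,
) -> SampleMetadata:
    """Host metadata with behavior scores linearly tied to ordination axis 2.

    ``pco2`` must be the axis-2 scores of the unweighted-UniFrac PCoA of
    the simulated OTU table (the cohort assembly computes it).  NW/OB are
    per-cluster Bernoulli draws; glucose/insulin skew insulin-resistant for
    OB; YFAS symptom counts are Poisson with a per-cluster rate and the
    diagnosis flag is only ever set with >= 3 symptoms.
    """
    rng = np.random.default_rng(config.rng_seed + 2)
    samples = list(truth.cluster.index)
    n = len(samples)
    cl_idx = {c: i for i, c in enumerate(CLUSTERS)}

    age = np.clip(rng.normal(35, 8, n), 18, 55)
    p_nw = np.array([config.nw_probability_per_cluster[cl_idx[c]] for c in truth.cluster])
    is_nw = rng.random(n) < p_nw
    weight_group = np.where(is_nw, "NW", "OB")

    x = pco2.loc[samples].to_numpy(dtype=float)
    noise = config.behavior_noise_sd
    ue = (config.ue_intercept + config.ue_slope * x
          + config.behavior_age_coef * age + rng.normal(0, noise, n))
    bite = (config.bite_intercept + config.bite_slope * x
            + config.behavior_age_coef * age + rng.normal(0, noise, n))

    rates = np.array([config.yfas_rate_per_cluster[cl_idx[c]] for c in truth.cluster])
    rates = np.where(is_nw, np.minimum(rates, 1.0), rates)
    yfas = rng.poisson(rates)
    diagnosis = (~is_nw) & (yfas >= 3) & (rng.random(n) < 0.6)

    glucose = np.where(is_nw, rng.normal(82, 5, n), rng.normal(89, 7, n))
    insulin = np.where(
        is_nw, np.exp(rng.normal(np.log(3.7), 0.3, n)), np.exp(rng.normal(np.log(10.0), 0.45, n))
    )
    bmi = np.where(is_nw, rng.normal(21.5, 1.5, n), rng.normal(31.0, 3.5, n))

    df = pd.DataFrame(
        {
            "weight_group": weight_group,
            "bmi": np.round(bmi, 1),
            "age": np.round(age, 1),
            "fasting_glucose": np.round(np.clip(glucose, 60, None), 1),
            "fasting_insulin": np.round(np.clip(insulin, 0.5, None), 2),
            "tfeq_ue": np.round(ue, 2),
            "tfeq_cr": np.round(rng.normal(14.3, 4.3, n), 2),
            "tfeq_ee": np.round(rng.normal(7.6, 3.0, n), 2),
            "bite_symptom": np.round(bite, 2),
            "bite_severity": np.round(np.clip(rng.normal(4.5, 4.5, n), 0, None), 2),
            "yfas_symptoms": yfas,
            "yfas_diagnosis": diagnosis,
            "pss": np.round(rng.normal(16.0, 5.9, n), 2),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    truth.behavior_slopes = {"tfeq_ue": config.ue_slope, "bite_symptom": config.bite_slope}
    truth.pco2 = pco2
    return SampleMetadata(df)


# ---------------------------------------------------------------------------
# diet
# ---------------------------------------------------------------------------

def food_annotations() -> pd.DataFrame:
    """Fixed per-item annotations; kcal is exactly the Atwater macro sum."""
    rng = np.random.default_rng(20_24)
    rows = []
    # archetype-relevant nutrient skeletons by food kind
    carby = {"bread", "pasta", "rice", "potatoes", "sweets", "soft_drinks"}
    proteiny = {"red_meat", "white_meat", "fish", "eggs", "cheese", "milk", "yogurt"}
    fatty = {"olive_oil", "butter", "nuts"}
    healthy = {"fruit", "vegetables", "legumes", "fish", "olive_oil", "nuts", "yogurt"}
    for item in FOOD_ITEMS:
        if item in carby:
            p, c, f = rng.uniform(2, 5), rng.uniform(25, 45), rng.uniform(1, 5)
        elif item in proteiny:
            p, c, f = rng.uniform(12, 25), rng.uniform(1, 8), rng.uniform(4, 15)
        elif item in fatty:
            p, c, f = rng.uniform(0, 4), rng.uniform(0, 4), rng.uniform(10, 15)
        else:
            p, c, f = rng.uniform(1, 4), rng.uniform(5, 15), rng.uniform(0, 2)
        fiber = rng.uniform(2, 6) if item in {"fruit", "vegetables", "legumes", "nuts"} else rng.uniform(0, 1.5)
        hv = rng.uniform(0.7, 1.0) if item in healthy else rng.uniform(0.1, 0.5)
        rows.append({"food": item, "kcal": 4 * p + 4 * c + 9 * f,
                     "protein_g": p, "carb_g": c, "fat_g": f,
                     "fiber_g": fiber, "health_value": hv})
    return pd.DataFrame(rows).set_index("food").round(3)


def _archetype_profiles() -> np.ndarray:
    """3 archetype profiles over the 20 foods (rows sum to 1).

    The archetypes sit along a single carbohydrate-to-fat dietary gradient
    (D1 low protein / high carbohydrate; D2 high protein / low carbohydrate,
    intermediate; D3 high fat / high protein) so the leading correspondence
    axis orders them, as an axis-1 grouping presumes.
    """
    idx = {f: i for i, f in enumerate(FOOD_ITEMS)}
    carb = np.full(len(FOOD_ITEMS), 1.0)
    for f in ("bread", "pasta", "rice", "potatoes", "sweets", "soft_drinks"):
        carb[idx[f]] = 7.0
    fat = np.full(len(FOOD_ITEMS), 1.0)
    for f in ("olive_oil", "butter", "nuts", "red_meat", "cheese"):
        fat[idx[f]] = 7.0
    mid = 0.5 * (carb + fat)
    for f in ("fish", "white_meat", "eggs", "yogurt"):
        mid[idx[f]] = 5.0
    base = np.vstack([carb, mid, fat])
    return base / base.sum(axis=1, keepdims=True)


def simulate_ffq(
    config: SynthConfig, truth: GroundTruth
) -> tuple[FeatureTable, pd.DataFrame]:
    """Per-sample food frequencies from Dirichlet-perturbed archetypes.

    The per-sample energy-intake factor is higher for clusters C2–C4.
    ``config.ffq_concentration = inf`` gives zero perturbation (each sample
    identical to its archetype profile).
    """
    rng = np.random.default_rng(config.rng_seed + 3)
    samples = list(truth.cluster.index)
    n = len(samples)
    profiles = _archetype_profiles()
    arch = rng.choice(3, size=n, p=config.diet_archetype_probs)
    freqs = np.zeros((n, len(FOOD_ITEMS)))
    conc = config.ffq_concentration
    for i in range(n):
        base = profiles[arch[i]]
        shares = base if not np.isfinite(conc) else rng.dirichlet(conc * base)
        energy_factor = 1.0 if truth.cluster.iloc[i] == "C1" else 1.15
        freqs[i] = shares * config.ffq_portions * energy_factor
    ffq = FeatureTable(pd.DataFrame(freqs, index=samples, columns=list(FOOD_ITEMS)),
                       level="food")
    truth.diet_archetype = pd.Series([f"A{a + 1}" for a in arch], index=samples,
                                     name="diet_archetype")
    return ffq, food_annotations()


# ---------------------------------------------------------------------------
# lipidome
# ---------------------------------------------------------------------------

def simulate_lipidome(config: SynthConfig, truth: GroundTruth) -> FeatureTable:
    """Log-normal lipid panels with cluster-patterned medians (ug/mg dry wt)."""
    rng = np.random.default_rng(config.rng_seed + 4)
    samples = list(truth.cluster.index)
    base_median = {lip: 10.0 ** rng.uniform(-0.5, 1.5) for lip in config.lipid_effects}
    data = {}
    for lip, effects in config.lipid_effects.items():
        mult = np.array([effects.get(c, 1.0) for c in truth.cluster])
        data[lip] = base_median[lip] * mult * np.exp(
            rng.normal(0.0, config.lipid_noise_sd, len(samples))
        )
    return FeatureTable(pd.DataFrame(data, index=samples), level="lipid")


# ---------------------------------------------------------------------------
# paired metatranscriptome / metagenome
# ---------------------------------------------------------------------------

def _resolve_expression_multipliers(
    targets: dict, proportions: tuple
) -> dict[tuple[str, str], dict[str, float]]:
    """Targets (cluster-over-cohort ratios) -> raw per-cluster multipliers.

    Unspecified clusters absorb the remainder so the proportion-weighted
    mean multiplier is 1; infeasible targets (remainder < 0) raise.
    """
    p = dict(zip(CLUSTERS, proportions))
    out = {}
    for key, spec in targets.items():
        specified = {c: float(r) for c, r in spec.items()}
        rest = [c for c in CLUSTERS if c not in specified]
        used = sum(p[c] * r for c, r in specified.items())
        if rest:
            remainder = (1.0 - used) / sum(p[c] for c in rest)
            if remainder < 0:
                raise ValidationError(
                    f"expression target {key} infeasible: specified ratios already "
                    f"exceed the cohort mean"
                )
            full = {c: specified.get(c, remainder) for c in CLUSTERS}
        else:
            if abs(used - 1.0) > 1e-6:
                raise ValidationError(f"expression target {key}: ratios must average to 1")
            full = specified
        out[key] = full
    return out


def simulate_transcriptome(
    config: SynthConfig,
    truth: GroundTruth,
    genus_rel: FeatureTable,
) -> PairedOmicsTable:
    """Paired RNA/DNA pathway tables stratified by species.

    DNA level = species abundance x a fixed species-by-feature incidence
    matrix x per-feature scale; RNA = DNA x E(species, feature, cluster) x
    log-normal noise.  Species abundances proxy the genus blocks (block
    sum), plus a low-abundance E. coli.  Species-unstratified totals are
    appended.  Zero-DNA entries are kept.
    """
    rng = np.random.default_rng(config.rng_seed + 5)
    samples = list(truth.cluster.index)
    n = len(samples)
    species = list(BLOCK_SPECIES.values()) + list(EXTRA_SPECIES)

    block_sum = {}
    for block, sp in BLOCK_SPECIES.items():
        cols = [g for g, b in truth.genus_block.items() if b == block]
        block_sum[sp] = genus_rel.data[cols].sum(axis=1).to_numpy()
    block_sum["Escherichia_coli"] = 0.01 * np.exp(rng.normal(0, 0.3, n))

    features = list(DEFAULT_PATHWAYS) + list(DEFAULT_KOS)
    struct = np.random.default_rng(config.rng_seed + 6)
    incidence = {
        (sp, f): bool(struct.random() < 0.7) for sp in species for f in features
    }
    # features carrying a planted signal are always present in their species
    for (sp, f) in config.expression_targets:
        incidence[(sp, f)] = True
    scale = {f: 10.0 ** struct.uniform(0.5, 2.0) for f in features}
    multipliers = _resolve_expression_multipliers(
        config.expression_targets, config.cluster_proportions
    )
    truth.expression_multipliers = multipliers

    keys, dna_rows, rna_rows = [], [], []
    cl = truth.cluster.to_numpy()
    for f in features:
        for sp in species:
            if not incidence[(sp, f)]:
                continue
            dna = block_sum[sp] * scale[f]
            e_by_cluster = multipliers.get((sp, f), {c: 1.0 for c in CLUSTERS})
            e = np.array([e_by_cluster[c] for c in cl])
            rna = dna * e * np.exp(rng.normal(0, config.expression_noise_sd, n))
            keys.append(f"{f}|{sp}")
            dna_rows.append(dna)
            rna_rows.append(rna)
    dna_mat = pd.DataFrame(np.array(dna_rows), index=keys, columns=samples)
    rna_mat = pd.DataFrame(np.array(rna_rows), index=keys, columns=samples)
    # unstratified totals
    for f in features:
        fkeys = [k for k in keys if k.startswith(f + "|")]
        dna_mat.loc[f] = dna_mat.loc[fkeys].sum()
        rna_mat.loc[f] = rna_mat.loc[fkeys].sum()
    rna_table = FeatureTable(rna_mat.T, level="pathway")
    dna_table = FeatureTable(dna_mat.T, level="pathway")
    return PairedOmicsTable(rna=rna_table, dna=dna_table)


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

def simulate_cohort(config: SynthConfig) -> dict:
    """Generate the full labeled cohort; returns all tables plus ground truth.

    The behavior scores are tied to the axis-2 scores of the unweighted
    UniFrac PCoA of the simulated OTU table, computed here with the same
    code the analysis stages use.
    """
    from .ordination import pcoa, unifrac

    tree, otu_genus = simulate_tree(config)
    otu_table, truth = simulate_abundances(config, otu_genus)
    rel = otu_table.relative()
    dm = unifrac(rel, tree, weighted=False)
    ordination = pcoa(dm)
    pco2 = ordination.coordinates["PCo2"]
    metadata = simulate_metadata(config, truth, pco2)
    ffq, annotations = simulate_ffq(config, truth)
    lipids = simulate_lipidome(config, truth)
    g_table = genus_table(otu_table, otu_genus).relative()
    paired = simulate_transcriptome(config, truth, g_table)
    return {
        "otu_table": otu_table,
        "tree": tree,
        "otu_genus": otu_genus,
        "genus_table": g_table,
        "metadata": metadata,
        "ffq": ffq,
        "food_annotations": annotations,
        "lipids": lipids,
        "paired": paired,
        "truth": truth,
        "ordination": ordination,
    }
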
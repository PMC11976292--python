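"""Synthetic data generators for every stage of the pipeline.

The generators emulate a two-group (tumour / normal kidney), multi-region
study design: each patient contributes several tumour regions plus normal
tissue, read-level epiallele data carry planted disorder differences
between groups, expression is linearly linked to promoter methylation and
epipolymorphism, bulk methylomes are convex mixtures of near-binary
component methylomes, and sample trees with additive distances support the
phylogenetics stage.  All randomness flows from one root seed through
named substreams, so a fixed seed reproduces every output exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .epiallele import ELocus, N_PATTERNS, epipolymorphism

PATTERN_ALL_UNMETH = 0
PATTERN_ALL_METH = N_PATTERNS - 1


def substream(seed: int, name: str) -> np.random.Generator:
    """Derive a named, reproducible random stream from the root seed."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    The defaults mirror the emulated design: 18 patients with multi-region
    tumour sampling plus normal kidney samples (136 samples in total), a
    fifth of e-loci carrying a planted disorder difference between groups,
    negative-binomial read depth around 30x, expression repressed by both
    promoter methylation and promoter disorder, and three-way cell-type
    mixtures.  ``disorder_high`` is the symmetric Dirichlet concentration
    for disordered (near-uniform) pattern vectors; ``disorder_low`` the
    concentration placed on a single pole pattern for ordered loci.
    """

    seed: int = 0
    n_patients: int = 18
    regions_per_patient: int = 6
    n_normal: int = 28
    n_eloci: int = 2000
    frac_differential: float = 0.2
    disorder_high: float = 10.0
    disorder_low: float = 100.0
    coverage_mean: float = 30.0
    coverage_dispersion: float = 5.0
    beta_meth: float = -2.0
    beta_epi: float = -1.0
    noise_sd: float = 0.5
    k_true: int = 3
    mixing_concentration: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_patients", "regions_per_patient", "n_normal", "n_eloci", "k_true"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0.0 <= self.frac_differential <= 1.0:
            raise ValueError("frac_differential must be in [0, 1]")
        for name in ("disorder_high", "disorder_low", "coverage_mean",
                     "coverage_dispersion", "mixing_concentration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class EpialleleSimulation:
    """Read-level epiallele data with planted group differences.

    ``counts`` has shape (n_eloci, n_samples, 16); zero total depth marks a
    locus missing in that sample.  ``truth`` records, per e-locus, whether
    a disorder difference was planted, which group is disordered, and the
    epipolymorphism of the realized pattern-probability vectors
    (``epi_tumour``, ``epi_normal``, ``delta_true`` = tumour - normal).
    ``pattern_probs`` holds those vectors, shape (n_eloci, 2, 16) with
    group axis ordered (tumour, normal).
    """

    eloci: list[ELocus]
    samples: pd.DataFrame  # sample_id, patient_id, group
    counts: np.ndarray
    truth: pd.DataFrame
    pattern_probs: np.ndarray

    @property
    def elocus_ids(self) -> list[str]:
        return [el.id for el in self.eloci]

    def counts_table(self) -> pd.DataFrame:
        """Tidy pattern-count table matching ``epiallele.count_patterns``."""
        n_loci, n_samples, _ = self.counts.shape
        idx = pd.MultiIndex.from_product(
            [self.elocus_ids, self.samples["sample_id"]],
            names=["elocus_id", "sample_id"],
        )
        flat = self.counts.reshape(n_loci * n_samples, N_PATTERNS).astype(int)
        return pd.DataFrame(flat, index=idx, columns=list(range(N_PATTERNS)))

    def profile_matrices(self) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        """(epipolymorphism, avg_methylation, depth) as loci x samples frames."""
        from .epiallele import avg_methylation

        sample_ids = self.samples["sample_id"].tolist()
        epi = pd.DataFrame(
            epipolymorphism(self.counts), index=self.elocus_ids, columns=sample_ids
        )
        meth = pd.DataFrame(
            avg_methylation(self.counts), index=self.elocus_ids, columns=sample_ids
        )
        depth = pd.DataFrame(
            self.counts.sum(axis=2), index=self.elocus_ids, columns=sample_ids
        )
        return epi, meth, depth

    def profiles(self) -> pd.DataFrame:
        """Tidy e-locus profile table (one row per locus/sample)."""
        from .epiallele import profiles_from_counts

        return profiles_from_counts(self.counts_table())


def _sample_table(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for p in range(config.n_patients):
        pid = f"P{p + 1:02d}"
        for r in range(config.regions_per_patient):
            rows.append((f"{pid}_T{r + 1}", pid, "tumour"))
    for i in range(config.n_normal):
        pid = f"P{(i % config.n_patients) + 1:02d}"
        rows.append((f"{pid}_N{i // config.n_patients + 1}", pid, "normal"))
    return pd.DataFrame(rows, columns=["sample_id", "patient_id", "group"])


def _ordered_vector(rng: np.random.Generator, pole: int, concentration: float) -> np.ndarray:
    """Dirichlet draw with nearly all mass on one pole pattern."""
    alpha = np.full(N_PATTERNS, 0.1)
    alpha[pole] = concentration
    return rng.dirichlet(alpha)


def simulate_epiallele_data(config: SimulationConfig) -> EpialleleSimulation:
    """Draw epiallele pattern counts for a two-group multi-region cohort.

    Non-differential e-loci share one pattern-probability vector across
    groups, drawn from a sparse symmetric Dirichlet (concentration 0.5),
    whose draws are usually dominated by a few patterns — emulating the
    mostly-concordant e-loci of real methylomes while keeping the
    per-sample disorder estimates non-degenerate.
    Differential e-loci receive a disordered, near-uniform vector in one
    group (half the time the tumour group, half the normal group) and an
    ordered pole vector in the other; the pole is all-methylated or
    all-unmethylated with equal probability, mirroring concordant
    hypo-/hypermethylation.  Reads are multinomial draws of the vector at
    negative-binomial depth; zero depth leaves the locus missing in that
    sample.
    """
    rng = substream(config.seed, "epialleles")
    samples = _sample_table(config)
    n_samples = len(samples)
    is_tumour = (samples["group"] == "tumour").to_numpy()

    L = config.n_eloci
    eloci = []
    spacing = 1000
    for i in range(L):
        start = 100 + i * spacing
        pos = (start, start + 12, start + 27, start + 45)
        eloci.append(ELocus(id=f"chrS:{pos[0]}-{pos[3]}", chrom="chrS", positions=pos))

    n_diff = int(round(config.frac_differential * L))
    diff_idx = rng.choice(L, size=n_diff, replace=False)
    is_diff = np.zeros(L, dtype=bool)
    is_diff[diff_idx] = True

    probs = np.empty((L, 2, N_PATTERNS))  # group axis: 0 = tumour, 1 = normal
    disordered_group = np.full(L, "", dtype=object)
    for i in range(L):
        if is_diff[i]:
            pole = PATTERN_ALL_METH if rng.random() < 0.5 else PATTERN_ALL_UNMETH
            dis = rng.dirichlet(np.full(N_PATTERNS, config.disorder_high))
            ordv = _ordered_vector(rng, pole, config.disorder_low)
            if rng.random() < 0.5:
                probs[i, 0], probs[i, 1] = dis, ordv
                disordered_group[i] = "tumour"
            else:
                probs[i, 0], probs[i, 1] = ordv, dis
                disordered_group[i] = "normal"
        else:
            probs[i, 0] = probs[i, 1] = rng.dirichlet(np.full(N_PATTERNS, 0.5))

    p_nb = config.coverage_dispersion / (config.coverage_dispersion + config.coverage_mean)
    depth = rng.negative_binomial(config.coverage_dispersion, p_nb, size=(L, n_samples))

    counts = np.zeros((L, n_samples, N_PATTERNS), dtype=np.int64)
    t_mask = is_tumour
    n_mask = ~is_tumour
    for i in range(L):
        counts[i, t_mask] = rng.multinomial(depth[i, t_mask], probs[i, 0])
        counts[i, n_mask] = rng.multinomial(depth[i, n_mask], probs[i, 1])

    epi_t = epipolymorphism(probs[:, 0, :])
    epi_n = epipolymorphism(probs[:, 1, :])
    truth = pd.DataFrame(
        {
            "elocus_id": [el.id for el in eloci],
            "differential": is_diff,
            "disordered_group": disordered_group,
            "epi_tumour": epi_t,
            "epi_normal": epi_n,
            "delta_true": epi_t - epi_n,
        }
    )
    return EpialleleSimulation(
        eloci=eloci, samples=samples, counts=counts, truth=truth, pattern_probs=probs
    )


def simulate_expression(
    meth: pd.DataFrame,
    epi: pd.DataFrame,
    config: SimulationConfig,
    effect_scale: str = "raw",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate log2 expression from promoter methylation and disorder.

    One gene is attached to each e-locus (row of ``meth`` / ``epi``,
    loci x samples, identically indexed):

        y = b0 + beta_meth * meth + beta_epi * epi + Normal(0, noise_sd)

    ``effect_scale='residual_sd'`` expresses the coefficients in
    residual-SD units of the signal each term uniquely contributes: the
    methylation coefficient is scaled by ``noise_sd / sd(meth)``, and the
    epipolymorphism coefficient by ``noise_sd / sd(epi orthogonal to
    meth)`` (epi residualized on methylation per gene), because the
    incremental, methylation-adjusted signal is what nested-model testing
    measures.  Returns (expression genes x samples, truth table of
    per-gene coefficients).
    """
    if effect_scale not in ("raw", "residual_sd"):
        raise ValueError("effect_scale must be 'raw' or 'residual_sd'")
    if not meth.index.equals(epi.index) or not meth.columns.equals(epi.columns):
        raise ValueError("meth and epi must share index and columns")
    rng = substream(config.seed, "expression")
    m = meth.to_numpy(dtype=float)
    e = epi.to_numpy(dtype=float)
    n_genes, n_samples = m.shape

    b0 = rng.normal(8.0, 2.0, size=n_genes)
    bm = np.full(n_genes, config.beta_meth)
    be = np.full(n_genes, config.beta_epi)
    if effect_scale == "residual_sd":
        sd_m = np.nanstd(m, axis=1, ddof=1)
        sd_e_perp = np.zeros(n_genes)
        for g in range(n_genes):
            ok = ~(np.isnan(m[g]) | np.isnan(e[g]))
            if ok.sum() < 4 or np.ptp(m[g][ok]) == 0:
                continue
            X = np.column_stack([np.ones(int(ok.sum())), m[g][ok]])
            beta_hat, _, _, _ = np.linalg.lstsq(X, e[g][ok], rcond=None)
            resid = e[g][ok] - X @ beta_hat
            sd_e_perp[g] = np.std(resid, ddof=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            bm = np.where(sd_m > 0, bm * config.noise_sd / sd_m, 0.0)
            be = np.where(sd_e_perp > 0, be * config.noise_sd / sd_e_perp, 0.0)

    noise = rng.normal(0.0, config.noise_sd, size=(n_genes, n_samples))
    y = b0[:, None] + bm[:, None] * m + be[:, None] * e + noise

    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]
    expr = pd.DataFrame(y, index=gene_ids, columns=meth.columns)
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "elocus_id": meth.index,
            "b0": b0,
            "beta_meth": bm,
            "beta_epi": be,
        }
    )
    return expr, truth


def simulate_mixture(
    config: SimulationConfig,
    n_features: int = 1000,
    n_samples: int = 60,
    noise_sd: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw a bulk methylation matrix as a convex mixture of methylomes.

    Component methylomes ``T0`` (features x k) sit near the 0/1 poles
    (Beta(1, 30) spread); proportions ``A0`` (k x samples) are Dirichlet
    columns on the simplex.  ``D = clip(T0 @ A0 + noise, 0, 1)``.
    Returns (D, T0, A0).
    """
    rng = substream(config.seed, "mixture")
    k = config.k_true
    pole = rng.random((n_features, k)) < 0.5
    spread = rng.beta(1.0, 30.0, size=(n_features, k))
    T0 = np.where(pole, 1.0 - spread, spread)
    A0 = rng.dirichlet(
        np.full(k, config.mixing_concentration), size=n_samples
    ).T
    D = T0 @ A0
    if noise_sd > 0:
        D = D + rng.normal(0.0, noise_sd, size=D.shape)
    return np.clip(D, 0.0, 1.0), T0, A0


def simulate_tree_data(
    n_leaves: int,
    seed: int,
    n_features: int = 50,
    brownian_sd: float = 1.0,
) -> tuple[dendropy.Tree, pd.DataFrame, pd.DataFrame]:
    """Random binary unrooted tree, its additive distances, and Brownian traits.

    The tree grows by attaching each new leaf to a uniformly chosen edge
    (the edge length is split; the pendant branch gets its own positive
    length), so the leaf-to-leaf path-length matrix is additive by
    construction.  Features evolve by Brownian motion along branches:
    child = parent + Normal(0, brownian_sd * sqrt(branch length)).

    Returns (tree, distance matrix as a labelled DataFrame, features as a
    leaves x features DataFrame).
    """
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    rng = substream(seed, "tree")
    labels = [f"S{i + 1}" for i in range(n_leaves)]
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)

    def pendant() -> float:
        return float(rng.uniform(0.2, 1.0))

    # start from the 3-leaf star, then attach remaining leaves to random edges
    for lab in labels[:3]:
        node = tree.seed_node.new_child(edge_length=pendant())
        node.taxon = tns.get_taxon(lab)
    for lab in labels[3:]:
        edges = [
            e
            for e in tree.preorder_edge_iter()
            if e.head_node is not tree.seed_node and e.length is not None
        ]
        edge = edges[rng.integers(len(edges))]
        parent, child = edge.tail_node, edge.head_node
        frac = float(rng.uniform(0.2, 0.8))
        total = edge.length
        parent.remove_child(child)
        mid = parent.new_child(edge_length=total * frac)
        mid.add_child(child)
        child.edge.length = total * (1.0 - frac)
        leaf = mid.new_child(edge_length=pendant())
        leaf.taxon = tns.get_taxon(lab)

    pdm = tree.phylogenetic_distance_matrix()
    dist = pd.DataFrame(0.0, index=labels, columns=labels)
    taxa = {t.label: t for t in tns}
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            d = pdm.patristic_distance(taxa[a], taxa[b])
            dist.loc[a, b] = dist.loc[b, a] = d

    values: dict[int, np.ndarray] = {id(tree.seed_node): np.zeros(n_features)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_val = values[id(node.parent_node)]
        step = rng.normal(0.0, brownian_sd * np.sqrt(node.edge.length), size=n_features)
        values[id(node)] = parent_val + step
    feats = pd.DataFrame(
        {leaf.taxon.label: values[id(leaf)] for leaf in tree.leaf_node_iter()}
    ).T
    feats = feats.loc[labels]
    feats.columns = [f"f{j + 1}" for j in range(n_features)]
    return tree, dist, feats
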
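"""Structured-cohort simulator: genotypes, covariates, traits, cohort splits.

Genotypes follow the Balding-Nichols F-model: each population's allele
frequency at a variant is a Beta draw around a shared ancestral frequency
``p`` with variance ``F_k * p * (1 - p)``, where ``F_k`` is the population's
divergence from the ancestral pool.  Under a star-shaped history the pairwise
differentiation between populations ``i`` and ``j`` is approximately
``(F_i + F_j) / 2``, which is how the pairwise matrix supplied by the user is
mapped to per-population divergences.

Traits are quantitative with three variance components on a unit scale:
a polygenic part from ``n_causal`` genotyped variants (share = heritability),
a population-structure part driven by a latent per-population ancestry score
(share = structure_effect; 0 gives a BMI-like non-structured trait), and
Gaussian noise absorbing the remainder; fixed-coefficient age/sex/batch
effects are added on the same scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)

_NON_PALINDROMIC_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]


# --------------------------------------------------------------------------- #
# models
# --------------------------------------------------------------------------- #
@dataclass
class PopulationModel:
    """Balding-Nichols population layout.

    ``fst_matrix`` holds pairwise differentiation (symmetric, zero diagonal,
    entries in [0, 1)); per-population divergences are recovered from it by
    least squares under the star approximation ``FST(i,j) = (F_i + F_j)/2``.
    ``pop_scores`` is the latent 1-D "geography" coordinate per population
    used as the trait confounder (ancestry score).
    """

    n_populations: int
    fst_matrix: np.ndarray
    n_variants: int = 5000
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 120_000_000, "2": 120_000_000}
    )
    pop_labels: list[str] | None = None
    pop_scores: np.ndarray | None = None
    # optional block-LD mode: adjacent-variant latent correlation within blocks
    ld_block_size: int = 1
    ld_rho: float = 0.0
    missing_rate: float = 0.0
    # per-population divergences, when known exactly (set by from_divergences);
    # otherwise recovered from fst_matrix by least squares
    divergences: np.ndarray | None = None
    # optional admixture-cline mode: population k's base frequency is the
    # mixture (1-a_k)*pA + a_k*pB of two diverged ancestral pools (pairwise
    # differentiation cline_fst), with the population's own drift on top.
    # This makes population contrasts share a common axis, so an external
    # panel can PARTIALLY span another cohort's internal structure.
    admixture: np.ndarray | None = None
    cline_fst: float = 0.0

    def __post_init__(self) -> None:
        self.fst_matrix = np.asarray(self.fst_matrix, dtype=float)
        k = self.n_populations
        if self.fst_matrix.shape != (k, k):
            raise ValueError("fst_matrix must be n_populations x n_populations")
        if not np.allclose(self.fst_matrix, self.fst_matrix.T):
            raise ValueError("fst_matrix must be symmetric")
        if np.any(np.diag(self.fst_matrix) != 0):
            raise ValueError("fst_matrix diagonal must be zero")
        if np.any(self.fst_matrix < 0) or np.any(self.fst_matrix >= 1):
            raise ValueError("fst_matrix entries must lie in [0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("ancestral_freq_range must be inside (0, 1)")
        if self.pop_labels is None:
            self.pop_labels = [f"pop{i}" for i in range(k)]
        if self.pop_scores is None:
            self.pop_scores = np.arange(k, dtype=float)
        self.pop_scores = np.asarray(self.pop_scores, dtype=float)
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")

    def population_divergences(self) -> np.ndarray:
        """Per-population F_k solving FST(i,j) ~= (F_i+F_j)/2, clipped to [0,1)."""
        if self.divergences is not None:
            return np.asarray(self.divergences, dtype=float)
        k = self.n_populations
        if k == 1:
            return np.zeros(1)
        rows, cols, rhs = [], [], []
        for i in range(k):
            for j in range(i + 1, k):
                rows.append(i)
                cols.append(j)
                rhs.append(self.fst_matrix[i, j])
        a = np.zeros((len(rhs), k))
        a[np.arange(len(rhs)), rows] = 0.5
        a[np.arange(len(rhs)), cols] = 0.5
        f, *_ = np.linalg.lstsq(a, np.asarray(rhs), rcond=None)
        return np.clip(f, 0.0, 1.0 - 1e-9)

    @classmethod
    def from_divergences(cls, divergences, **kwargs) -> "PopulationModel":
        """Build a model from per-population F_k (star phylogeny)."""
        f = np.asarray(divergences, dtype=float)
        mat = (f[:, None] + f[None, :]) / 2.0
        np.fill_diagonal(mat, 0.0)
        return cls(n_populations=len(f), fst_matrix=mat, divergences=f, **kwargs)

    @classmethod
    def from_cline(
        cls, admixture, own_divergences, cline_fst: float, **kwargs
    ) -> "PopulationModel":
        """Build an admixture-cline model.

        ``admixture`` gives each population's mixing proportion a_k of the
        second ancestral pool; ``own_divergences`` the population-specific
        drift F_k on top of the cline.  Pairwise differentiation is
        approximately ``(F_i + F_j)/2 + (a_i - a_j)^2 * cline_fst / 2``.
        """
        a = np.asarray(admixture, dtype=float)
        f = np.asarray(own_divergences, dtype=float)
        if a.shape != f.shape:
            raise ValueError("admixture and own_divergences must align")
        mat = (f[:, None] + f[None, :]) / 2.0 + (
            (a[:, None] - a[None, :]) ** 2
        ) * cline_fst / 2.0
        np.fill_diagonal(mat, 0.0)
        return cls(
            n_populations=len(f), fst_matrix=np.clip(mat, 0, 1 - 1e-9),
            divergences=f, admixture=a, cline_fst=cline_fst, **kwargs
        )


@dataclass
class TraitModel:
    """Variance-share specification of a simulated quantitative trait."""

    heritability: float = 0.3
    n_causal: int = 200
    structure_effect: float = 0.0
    covariate_effects: dict[str, float] = field(default_factory=dict)
    noise_sd: float | None = None
    name: str = "trait"

    def __post_init__(self) -> None:
        if not 0 <= self.heritability <= 1:
            raise ValueError("heritability must be in [0, 1]")
        if not 0 <= self.structure_effect <= 1:
            raise ValueError("structure_effect must be in [0, 1]")


@dataclass
class CohortSplit:
    """Disjoint sample-role assignment for the discovery/target/panel design."""

    discovery_ids: np.ndarray
    target_same_ids: np.ndarray
    target_other_ids: np.ndarray
    external_panels: dict[str, np.ndarray]

    @property
    def external_panel_ids(self) -> np.ndarray:
        """Union of all external panel samples."""
        out: list = []
        seen = set()
        for ids in self.external_panels.values():
            for s in ids:
                if s not in seen:
                    seen.add(s)
                    out.append(s)
        return np.asarray(out, dtype=object)

    def validate_disjoint(self) -> None:
        """Error unless the four role groups are pairwise disjoint."""
        groups = {
            "discovery": set(self.discovery_ids),
            "target_same": set(self.target_same_ids),
            "target_other": set(self.target_other_ids),
            "external_panel": set(self.external_panel_ids),
        }
        names = list(groups)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                overlap = groups[a] & groups[b]
                if overlap:
                    raise ValueError(
                        f"roles {a!r} and {b!r} share samples, e.g. "
                        f"{sorted(overlap)[:5]}"
                    )


# --------------------------------------------------------------------------- #
# genotype simulation
# --------------------------------------------------------------------------- #
def _assign_positions(model: PopulationModel, rng: np.random.Generator) -> pd.DataFrame:
    chroms = list(model.chrom_lengths)
    lengths = np.array([model.chrom_lengths[c] for c in chroms], dtype=float)
    counts = np.floor(model.n_variants * lengths / lengths.sum()).astype(int)
    counts[0] += model.n_variants - counts.sum()
    rows = []
    for chrom, cnt in zip(chroms, counts):
        span = model.chrom_lengths[chrom]
        pos = np.unique(rng.integers(1, span + 1, size=cnt))
        while len(pos) < cnt:  # resample collisions (rare for span >> cnt)
            extra = rng.integers(1, span + 1, size=cnt - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        rows.append(pd.DataFrame({"chrom": chrom, "pos": np.sort(pos)}))
    df = pd.concat(rows, ignore_index=True)
    pair_idx = rng.integers(0, len(_NON_PALINDROMIC_PAIRS), size=len(df))
    df["allele1"] = [_NON_PALINDROMIC_PAIRS[i][0] for i in pair_idx]
    df["allele2"] = [_NON_PALINDROMIC_PAIRS[i][1] for i in pair_idx]
    df.insert(0, "variant_id", [f"var{i:06d}" for i in range(len(df))])
    return df


def _population_frequencies(
    model: PopulationModel, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral freqs (m,) and per-population freqs (K, m)."""
    lo, hi = model.ancestral_freq_range
    m = model.n_variants
    p_anc = rng.uniform(lo, hi, size=m)
    divergences = model.population_divergences()

    def beta_around(mean, f):
        # Balding-Nichols draw: mean ``mean``, variance f*mean*(1-mean)
        if f <= 0:
            return mean.copy()
        a = mean * (1.0 - f) / f
        b = (1.0 - mean) * (1.0 - f) / f
        return rng.beta(a, b)

    if model.admixture is not None:
        pool_a = p_anc
        pool_b = np.clip(beta_around(p_anc, model.cline_fst), 1e-6, 1 - 1e-6)
        bases = [
            (1.0 - alpha) * pool_a + alpha * pool_b
            for alpha in model.admixture
        ]
    else:
        bases = [p_anc] * model.n_populations

    freqs = np.empty((model.n_populations, m))
    for k, f in enumerate(divergences):
        freqs[k] = beta_around(np.clip(bases[k], 1e-6, 1 - 1e-6), f)
    return p_anc, np.clip(freqs, 1e-12, 1 - 1e-12)


def _draw_haplotypes(
    pop_freqs_row: np.ndarray, n: int, model: PopulationModel, rng: np.random.Generator
) -> np.ndarray:
    """n x m genotypes for one population, optionally with block-LD."""
    m = len(pop_freqs_row)
    if model.ld_rho == 0.0 or model.ld_block_size <= 1:
        return rng.binomial(2, pop_freqs_row, size=(n, m)).astype(np.float64)
    # Gaussian-copula haplotypes: AR(1) latent within blocks, thresholded at
    # the allele frequency, so adjacent variants are positively correlated.
    from scipy.stats import norm

    thresh = norm.ppf(pop_freqs_row)
    geno = np.zeros((n, m), dtype=np.float64)
    rho = model.ld_rho
    bs = model.ld_block_size
    for _hap in range(2):
        z = rng.standard_normal((n, m))
        for start in range(0, m, bs):
            stop = min(start + bs, m)
            for j in range(start + 1, stop):
                z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * z[:, j]
        geno += (z < thresh).astype(np.float64)
    return geno


def simulate_genotypes(
    model: PopulationModel, n_per_pop, seed: int
) -> GenotypeMatrix:
    """Draw a structured genotype matrix under the Balding-Nichols model.

    Deterministic under a fixed ``seed``.  ``n_per_pop`` gives the number of
    samples per population (scalar or one count per population).
    """
    rng = np.random.default_rng(seed)
    n_per_pop = np.broadcast_to(
        np.asarray(n_per_pop, dtype=int), (model.n_populations,)
    )
    if np.any(n_per_pop <= 0):
        raise ValueError("n_per_pop entries must be positive")

    variants = _assign_positions(model, rng)
    _, pop_freqs = _population_frequencies(model, rng)

    blocks, labels = [], []
    for k in range(model.n_populations):
        blocks.append(_draw_haplotypes(pop_freqs[k], int(n_per_pop[k]), model, rng))
        labels.extend([model.pop_labels[k]] * int(n_per_pop[k]))
    dosages = np.vstack(blocks)

    if model.missing_rate > 0:
        mask = rng.random(dosages.shape) < model.missing_rate
        dosages[mask] = np.nan

    n_total = dosages.shape[0]
    sample_ids = np.array([f"S{i:06d}" for i in range(n_total)], dtype=object)
    info = pd.DataFrame({"sample_id": sample_ids, "population": labels})
    return GenotypeMatrix(dosages, variants, sample_ids, info)


def simulate_covariates(
    geno: GenotypeMatrix, model: PopulationModel, seed: int
) -> pd.DataFrame:
    """Sample table: population label, age, sex, batch, latent ancestry score."""
    rng = np.random.default_rng(seed)
    if geno.sample_info is None or "population" not in geno.sample_info:
        raise ValueError("genotype matrix lacks population labels")
    pops = geno.sample_info["population"].to_numpy()
    score_of = dict(zip(model.pop_labels, model.pop_scores))
    n = geno.n_samples
    return pd.DataFrame(
        {
            "sample_id": geno.sample_ids,
            "population": pops,
            "age": rng.integers(40, 71, size=n),
            "sex": rng.integers(0, 2, size=n),
            "batch": np.where(rng.random(n) < 0.5, "batchA", "batchB"),
            "ancestry_score": np.array([score_of[p] for p in pops], dtype=float),
        }
    )


# --------------------------------------------------------------------------- #
# trait simulation
# --------------------------------------------------------------------------- #
def simulate_trait(
    geno: GenotypeMatrix,
    samples: pd.DataFrame,
    model: TraitModel,
    seed: int,
) -> tuple[np.ndarray, dict]:
    """Simulate a quantitative trait; returns (trait, truth record).

    The polygenic and ancestry components are rescaled to their exact
    empirical variance shares so the realized architecture matches the model.
    The truth record carries causal indices, per-allele effects, and realized
    variance shares.
    """
    rng = np.random.default_rng(seed)
    n = geno.n_samples
    if len(samples) != n:
        raise ValueError("sample table and genotype matrix sizes differ")
    if model.n_causal > geno.n_variants:
        raise ValueError("n_causal exceeds n_variants")

    causal_idx = np.sort(rng.choice(geno.n_variants, size=model.n_causal, replace=False))
    g = geno.dosages[:, causal_idx]
    if np.isnan(g).any():
        raise ValueError("causal variants must have complete genotypes")

    betas = rng.standard_normal(model.n_causal)
    gscore = g @ betas
    # Causal allele-frequency drift gives the raw score a random
    # between-population mean shift; remove it so the trait's ancestry
    # correlation is controlled by structure_effect alone (the generator's
    # contract), not by a lucky draw of beta-vs-drift alignment.
    if "population" in samples.columns:
        pops = samples["population"].to_numpy()
        pop_means = pd.Series(gscore).groupby(pops).transform("mean").to_numpy()
        gscore = gscore - pop_means
    sd_g = gscore.std()
    if model.heritability > 0 and sd_g > 0:
        scale_g = np.sqrt(model.heritability) / sd_g
    else:
        scale_g = 0.0
    genetic = (gscore - gscore.mean()) * scale_g

    anc = samples["ancestry_score"].to_numpy(dtype=float)
    sd_a = anc.std()
    if model.structure_effect > 0 and sd_a > 0:
        structure = (anc - anc.mean()) / sd_a * np.sqrt(model.structure_effect)
    else:
        structure = np.zeros(n)

    cov_term = np.zeros(n)
    eff = model.covariate_effects
    if eff.get("age"):
        cov_term += eff["age"] * samples["age"].to_numpy(dtype=float)
    if eff.get("sex"):
        cov_term += eff["sex"] * samples["sex"].to_numpy(dtype=float)
    if eff.get("batch"):
        cov_term += eff["batch"] * (samples["batch"].to_numpy() == "batchB")
    cov_var = cov_term.var()

    share_sum = model.heritability + model.structure_effect + cov_var
    if share_sum > 1 + 1e-9:
        raise ValueError(
            f"variance shares exceed 1: heritability={model.heritability}, "
            f"structure={model.structure_effect}, covariates={cov_var:.4f}"
        )
    if model.noise_sd is not None:
        noise_sd = model.noise_sd
    else:
        noise_sd = float(np.sqrt(max(0.0, 1.0 - share_sum)))
    noise = rng.standard_normal(n) * noise_sd

    trait = genetic + structure + cov_term + noise
    total_var = trait.var()
    truth = {
        "name": model.name,
        "causal_idx": causal_idx,
        "causal_variant_ids": geno.variants["variant_id"].to_numpy()[causal_idx],
        "betas": betas * scale_g,
        "genetic_score": genetic,
        "realized_shares": {
            "genetic": float(genetic.var() / total_var) if total_var else 0.0,
            "structure": float(structure.var() / total_var) if total_var else 0.0,
            "covariates": float(cov_var / total_var) if total_var else 0.0,
            "noise": float(noise.var() / total_var) if total_var else 0.0,
        },
        "noise_sd": noise_sd,
    }
    logger.info("trait %s realized variance shares: %s", model.name,
                truth["realized_shares"])
    return trait, truth


# --------------------------------------------------------------------------- #
# cohort splitting
# --------------------------------------------------------------------------- #
_CORE_ROLES = ("discovery", "target_same", "target_other")


def split_cohorts(
    samples: pd.DataFrame,
    sizes: dict[str, int],
    seed: int,
    populations: dict[str, list[str]] | None = None,
) -> CohortSplit:
    """Randomly assign samples to disjoint roles.

    ``sizes`` maps role names to counts; names outside the three core roles
    (discovery / target_same / target_other) become external PC panels.
    ``populations`` optionally restricts a role to given population labels.
    """
    rng = np.random.default_rng(seed)
    populations = populations or {}
    available: dict[str, list] = {}
    by_pop = samples.groupby("population")["sample_id"].apply(list).to_dict()
    for pop, ids in by_pop.items():
        available[pop] = list(ids)

    assigned: dict[str, np.ndarray] = {}
    for role, n_req in sizes.items():
        allowed = populations.get(role)
        pool: list = []
        for pop, ids in available.items():
            if allowed is None or pop in allowed:
                pool.extend(ids)
        if n_req > len(pool):
            raise ValueError(
                f"role {role!r} requests {n_req} samples, only {len(pool)} available"
            )
        pool = np.array(sorted(pool), dtype=object)
        chosen = rng.choice(pool, size=n_req, replace=False)
        assigned[role] = np.sort(chosen)
        chosen_set = set(chosen)
        for pop in available:
            available[pop] = [s for s in available[pop] if s not in chosen_set]

    panels = {r: ids for r, ids in assigned.items() if r not in _CORE_ROLES}
    split = CohortSplit(
        discovery_ids=assigned.get("discovery", np.array([], dtype=object)),
        target_same_ids=assigned.get("target_same", np.array([], dtype=object)),
        target_other_ids=assigned.get("target_other", np.array([], dtype=object)),
        external_panels=panels,
    )
    split.validate_disjoint()
    return split


# --------------------------------------------------------------------------- #
# paper-emulation preset
# --------------------------------------------------------------------------- #
#: study-design reference counts for the target/panel roles (scaled by the
#: preset's scale factor); the discovery size is set separately because the
#: original design's discovery set is far larger than desk scale permits.
_EMULATION_ROLE_COUNTS = {
    "target_same": 7100,
    "target_other": 7070,
    "panel_cohort_same": 5000,
    "panel_cohort_other": 5000,
    "panel_european": 503,
    "panel_non_european": 2001,
}


def paper_emulation_preset(
    scale: float = 0.2,
    discovery_n: int = 8000,
    n_variants: int = 20000,
    seed: int = 0,
):
    """Population model + role sizes emulating the two-biobank study design.

    Five populations on an admixture cline between two diverged ancestral
    pools: two close "British-like" subpopulations (the internal structure
    of the discovery cohort and its same-population target), an
    "Estonian-like" population for the second target cohort, an
    "other-European" population, and a diverged "non-European" population.
    Because every population mixes the same two pools, part of the discovery
    cohort's internal axis is a *shared* continental direction that external
    reference panels can capture, while the population-specific drift on top
    of it is invisible to them — which is exactly why projection-based PC
    correction is only partial.  The European reference panel mixes the four
    European-like populations (as a continental panel with some discovery-
    population representation would); the all-populations panel is the union
    of the European and non-European panels.

    Returns ``(model, sizes, populations)`` ready for :func:`split_cohorts`;
    the ``all_reference`` panel is assembled downstream as the union of the
    ``panel_european`` and ``panel_non_european`` roles.
    """
    # Admixture coordinates: the two discovery subpopulations sit close on
    # the continental cline (small delta-alpha), so an external panel's
    # cline-derived PCs are only a PARTIAL proxy for their membership, while
    # most of their differentiation is population-specific drift that only a
    # cohort-specific panel can see.
    alphas = [0.0, 0.03, 0.10, 0.30, 1.0]
    own_f = [0.002, 0.006, 0.002, 0.004, 0.02]
    cline_fst = 0.15
    labels = ["brit_a", "brit_b", "est", "eur_other", "non_eur"]
    # trait geography: correlated with, but not proportional to, admixture
    scores = np.array([0.0, 1.0, 1.5, 2.5, 3.5])
    sizes = {"discovery": discovery_n}
    for role, count in _EMULATION_ROLE_COUNTS.items():
        sizes[role] = max(30, int(round(count * scale)))
    populations = {
        "discovery": ["brit_a", "brit_b"],
        "target_same": ["brit_a", "brit_b"],
        "target_other": ["est"],
        "panel_cohort_same": ["brit_a", "brit_b"],
        "panel_cohort_other": ["est"],
        # the continental reference panel does NOT sample the discovery
        # cohort's internal subpopulations; it sees their shared cline only
        "panel_european": ["est", "eur_other"],
        "panel_non_european": ["non_eur"],
    }
    model = PopulationModel.from_cline(
        alphas,
        own_f,
        cline_fst,
        n_variants=n_variants,
        pop_labels=labels,
        pop_scores=scores,
    )
    return model, sizes, populations


def emulation_pop_sizes(sizes: dict[str, int], populations: dict[str, list[str]],
                        margin: float = 1.15) -> dict[str, int]:
    """Per-population sample counts large enough to fill every role."""
    need: dict[str, float] = {}
    for role, n in sizes.items():
        pops = populations.get(role)
        if pops is None:
            continue
        for p in pops:
            need[p] = need.get(p, 0.0) + n / len(pops)
    return {p: int(np.ceil(v * margin)) + 10 for p, v in need.items()}
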
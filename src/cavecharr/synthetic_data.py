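"""Synthetic study generator with known ground truth.

Generates the four input layers the analysis pipeline consumes — diploid
microsatellite genotypes for cave populations founded from one source,
cave-level environments, individual phenotypes/landmarks with allometry, and
two-session capture histories — under the statistical structure the analysis
assumes, so every downstream stage can be verified by recovery tests.

Drift is modelled at the allele-frequency level: each population's gene pool
is a sequence of multinomial draws (founding draw of ``2 * founders`` genes,
then ``2 * pop_size`` genes per generation), with configured migration pairs
exchanging individuals (frequency-level mixing) before reproduction.
``generations`` counts the total number of multinomial sampling events
including the founding draw, so with ``founders_per_pop == pop_size = N``
heterozygosity decays exactly as ``(1 - 1/(2N))^generations`` in expectation
and ``generations = 0`` reproduces the source frequencies unchanged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import GenotypeTable, LandmarkSet
from .popgen import chord_distance_from_frequencies
from .varpart import SimilarityMatrix, similarity_from_distance, env_variance

__all__ = [
    "LocusSpec",
    "TraitParams",
    "SimulationConfig",
    "SimulationTruth",
    "default_config",
    "default_template",
    "default_deformation_basis",
    "trait_params_for_proportions",
    "simulate_source_frequencies",
    "simulate_colonization",
    "simulate_environment",
    "simulate_phenotypes",
    "simulate_landmarks",
    "simulate_capture_histories",
    "simulate_study",
    "write_study",
    "drift_fixation_index",
]

#: genotyped sample sizes of the 24 cave populations in the field survey
CAVE_SAMPLE_SIZES = (26, 30, 15, 17, 56, 15, 78, 9, 21, 30, 48, 42,
                     14, 10, 16, 60, 26, 43, 35, 71, 38, 22, 182, 69)
#: genotyped sample sizes of the two source (lake) collections
SOURCE_SAMPLE_SIZES = {"Lake-G": 50, "Lake-K": 49}

#: geographic subareas of the 24 caves (two areas, five clusters); caves in a
#: subarea are genetically clustered, which the default migration scheme
#: emulates with low within-subarea gene flow
SUBAREAS = {
    "H-S": ["C1", "C2", "C3", "C4"],
    "H-N": ["C5", "C6", "C7", "C8"],
    "H-C": ["C9", "C10", "C11", "C12", "C13", "C14"],
    "V-W": ["C15", "C16", "C17", "C18", "C19"],
    "V-E": ["C20", "C21", "C22", "C23"],
    # C24 sits between clusters and is left unconnected
}

#: six observed inter-cave mover pairs (counts span 1-19, mean ~6.7)
OBSERVED_MOVER_PAIRS = [
    ("C1", "C2", 10), ("C9", "C10", 19), ("C5", "C6", 3),
    ("C12", "C13", 5), ("C16", "C17", 2), ("C20", "C21", 1),
]


def _default_migration_pairs() -> list:
    """Within-subarea chain migration (2/generation) with the observed mover
    pairs overriding the affected edges."""
    overrides = {frozenset((a, b)): m for a, b, m in OBSERVED_MOVER_PAIRS}
    pairs = []
    for caves in SUBAREAS.values():
        for a, b in zip(caves[:-1], caves[1:]):
            pairs.append((a, b, overrides.pop(frozenset((a, b)), 2)))
    for key, m in overrides.items():
        a, b = sorted(key)
        pairs.append((a, b, m))
    return pairs


@dataclass
class LocusSpec:
    name: str
    n_alleles: int
    concentration: float = 0.6

    def __post_init__(self):
        if self.n_alleles < 2:
            raise ValueError(f"locus {self.name}: need >= 2 alleles")
        if self.concentration <= 0:
            raise ValueError(f"locus {self.name}: concentration must be positive")


@dataclass
class TraitParams:
    """Generative analogues of the mixed model's fixed and random parameters."""

    alpha: float = 0.0
    beta_L: float = 0.0
    beta_T: float = 0.0
    beta_O: float = 0.0
    beta_D: float = 0.0
    delta_T: float = 0.0
    delta_O: float = 0.0
    delta_D: float = 0.0
    var_gen: float = 0.0
    var_gen_slope: float = 0.0
    var_cave: float = 0.0
    var_cave_slope: float = 0.0
    var_resid: float = 1.0

    def __post_init__(self):
        for f in ("var_gen", "var_gen_slope", "var_cave", "var_cave_slope", "var_resid"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")


@dataclass
class SimulationConfig:
    n_populations: int = 24
    loci: list = field(default_factory=lambda: [
        LocusSpec(name, 8, 0.6) for name in (
            "OMM1236", "OMM1329", "OMM1302", "BX890355", "Omi179TUF",
            "OMM1228", "OMM5151", "OMM5146", "OMM1211")
    ])
    founders_per_pop: int = 25
    generations: int = 50
    pop_size: int | list = 100
    samples_per_pop: int | list = field(default_factory=lambda: list(CAVE_SAMPLE_SIZES))
    source_samples: dict = field(default_factory=lambda: dict(SOURCE_SAMPLE_SIZES))
    # each entry: (pop_a, pop_b, migrants exchanged per generation); None
    # selects the subarea scheme at full scale and no migration otherwise
    migration_pairs: list | None = None
    env_ranges: dict = field(default_factory=lambda: {
        "temperature": (5.52, 0.7),       # Normal(mean, sd) degrees C
        "openings": (1, 7),               # uniform integer
        "distance": (57.0, 500.0),        # uniform metres from the lake
    })
    trait_params: TraitParams = field(default_factory=lambda: TraitParams(
        beta_L=0.3, beta_T=0.55, var_gen=0.3, var_cave=0.4,
        var_gen_slope=0.05, var_cave_slope=0.05, var_resid=1.0))
    individuals_per_pop_phenotype: int = 30
    capture_prob: float = 0.5
    seed: int | None = None

    def __post_init__(self):
        if self.n_populations < 1:
            raise ValueError("need at least one population")
        if self.migration_pairs is None:
            self.migration_pairs = (
                _default_migration_pairs() if self.n_populations == 24 else []
            )
        if self.founders_per_pop < 1 or self.generations < 0:
            raise ValueError("counts must be >= 1 (generations >= 0)")
        sizes = self.pop_sizes()
        if any(s < 1 for s in sizes):
            raise ValueError("population sizes must be >= 1")
        if any(self.founders_per_pop > s for s in sizes):
            raise ValueError("founders_per_pop cannot exceed pop_size")
        if not (0 < self.capture_prob <= 1):
            raise ValueError("capture_prob must be in (0, 1]")
        names = set(self.population_names())
        for a, b, m in self.migration_pairs:
            if a not in names or b not in names:
                raise ValueError(f"migration pair ({a}, {b}) references unknown population")
            if m < 0:
                raise ValueError("migrant count must be >= 0")

    def population_names(self) -> list[str]:
        return [f"C{i + 1}" for i in range(self.n_populations)]

    def pop_sizes(self) -> list[int]:
        if isinstance(self.pop_size, int):
            return [self.pop_size] * self.n_populations
        return list(self.pop_size)

    def sample_sizes(self) -> list[int]:
        if isinstance(self.samples_per_pop, int):
            return [self.samples_per_pop] * self.n_populations
        sizes = list(self.samples_per_pop)
        if len(sizes) < self.n_populations:
            raise ValueError("samples_per_pop shorter than n_populations")
        return sizes[: self.n_populations]


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside the generated data."""

    source_frequencies: list = None
    frequency_trajectories: dict = None   # pop -> (G+1, L, A_max) arrays
    terminal_frequencies: dict = None
    similarity: SimilarityMatrix = None
    census_sizes: dict = None
    migrants: list = None
    cave_effects: dict = None             # g_a, g_b, c_a, c_b per population
    proportions: dict = None              # true E, G, O of the trait
    variance_components: dict = None
    stage_seeds: dict = field(default_factory=dict)


def default_config() -> SimulationConfig:
    """Study-scale defaults: 24 caves plus two source collections."""
    return SimulationConfig()


# ---------------------------------------------------------------------------
# genetics

def simulate_source_frequencies(loci, seed=None) -> list[np.ndarray]:
    """Dirichlet allele-frequency vectors for the source (lake) population."""
    rng = np.random.default_rng(seed)
    freqs = []
    for spec in loci:
        if spec.n_alleles < 2 or spec.concentration <= 0:
            raise ValueError("invalid locus specification")
        f = rng.dirichlet(np.full(spec.n_alleles, spec.concentration))
        freqs.append(f / f.sum())
    return freqs


def _hw_genotypes(freqs: list[np.ndarray], n: int, rng) -> np.ndarray:
    """(n, L, 2) Hardy–Weinberg genotype draws from per-locus frequencies."""
    out = np.zeros((n, len(freqs), 2), dtype=np.int64)
    for l, f in enumerate(freqs):
        out[:, l, :] = rng.choice(np.arange(1, f.size + 1), size=(n, 2), p=f)
    return out


def simulate_colonization(source_freqs, config: SimulationConfig,
                          seed=None) -> tuple[GenotypeTable, SimulationTruth]:
    """Found and drift the cave populations; return genotypes plus truth.

    Each cave starts from a multinomial founding draw of ``2 * founders``
    genes from the source pool; subsequent generations are multinomial draws
    of ``2 * pop_size`` genes from the parental (post-migration) frequencies.
    Terminal genotype samples are Hardy–Weinberg pairs; source collections
    configured in ``source_samples`` are drawn directly from the source
    frequencies.
    """
    if config.n_populations < 1:
        raise ValueError("zero populations")
    rng = np.random.default_rng(seed)
    pops = config.population_names()
    sizes = config.pop_sizes()
    n_loci = len(source_freqs)
    a_max = max(f.size for f in source_freqs)

    def pad(freqs):
        arr = np.zeros((n_loci, a_max))
        for l, f in enumerate(freqs):
            arr[l, : f.size] = f
        return arr

    source = pad(source_freqs)
    traj = {p: [source.copy()] for p in pops}
    current = {p: source.copy() for p in pops}

    def drift(freq_arr, genes):
        out = np.zeros_like(freq_arr)
        for l in range(n_loci):
            out[l] = rng.multinomial(genes, freq_arr[l] / freq_arr[l].sum()) / genes
        return out

    if config.generations >= 1:
        for p, n_pop in zip(pops, sizes):
            current[p] = drift(current[p], 2 * config.founders_per_pop)
            traj[p].append(current[p].copy())
            del n_pop
        for _ in range(config.generations - 1):
            # symmetric migrant exchange before reproduction
            for a, b, m in config.migration_pairs:
                if m == 0:
                    continue
                na = sizes[pops.index(a)]
                nb = sizes[pops.index(b)]
                fa, fb = current[a], current[b]
                current[a] = fa * (na - m) / na + fb * m / na
                current[b] = fb * (nb - m) / nb + fa * m / nb
            for p, n_pop in zip(pops, sizes):
                current[p] = drift(current[p], 2 * n_pop)
                traj[p].append(current[p].copy())

    rows, pop_labels, ids = [], [], []
    for p, n_sample in zip(pops, config.sample_sizes()):
        freqs = [current[p][l] for l in range(n_loci)]
        geno = _hw_genotypes(freqs, n_sample, rng)
        rows.append(geno)
        pop_labels.extend([p] * n_sample)
        ids.extend(f"{p}_i{k + 1}" for k in range(n_sample))
    for name, n_sample in config.source_samples.items():
        geno = _hw_genotypes([source[l] for l in range(n_loci)], n_sample, rng)
        rows.append(geno)
        pop_labels.extend([name] * n_sample)
        ids.extend(f"{name}_i{k + 1}" for k in range(n_sample))
    gt = GenotypeTable(np.vstack(rows), np.array(pop_labels, dtype=object),
                       np.array(ids, dtype=object),
                       [s.name for s in config.loci[:n_loci]])

    terminal = {p: current[p] for p in pops}
    # true similarity from terminal true frequencies via the same Dce -> S map
    freq_stack = np.stack([terminal[p] for p in pops])
    usable = np.ones((len(pops), n_loci), dtype=bool)
    dce = chord_distance_from_frequencies(freq_stack, usable, pops)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        similarity = similarity_from_distance(dce)
    truth = SimulationTruth(
        source_frequencies=[source[l].copy() for l in range(n_loci)],
        frequency_trajectories={p: np.stack(traj[p]) for p in pops},
        terminal_frequencies=terminal,
        similarity=similarity,
        census_sizes=dict(zip(pops, sizes)),
        migrants=list(config.migration_pairs),
    )
    return gt, truth


def drift_fixation_index(truth: SimulationTruth) -> float:
    """Realized drift F of the caves: standardized variance around the source.

    ``F = sum_l sum_a (p_terminal - p_source)^2 / sum_l sum_a p_source (1 -
    p_source)``, averaged over populations.  Under pure multinomial drift its
    expectation is ``1 - (1 - 1/(2N))^G``.
    """
    src = np.stack(truth.source_frequencies)
    denom = np.sum(src * (1 - src))
    vals = []
    for p, term in truth.terminal_frequencies.items():
        vals.append(np.sum((term - src) ** 2) / denom)
        del p
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# environment

def simulate_environment(n_populations: int, ranges: dict | None = None,
                         seed=None) -> pd.DataFrame:
    """Cave-level covariates and coordinates.

    Temperature is Normal, openings a uniform integer, distance to the lake
    uniform; coordinates are placed in two geographic clusters (areas "H"
    and "V").  Constant covariate columns (zero spread) are flagged in
    ``df.attrs['constant_columns']``.
    """
    if n_populations < 1:
        raise ValueError("need n >= 1")
    ranges = dict(ranges or {})
    t_mean, t_sd = ranges.get("temperature", (5.52, 0.7))
    o_lo, o_hi = ranges.get("openings", (1, 7))
    d_lo, d_hi = ranges.get("distance", (57.0, 500.0))
    rng = np.random.default_rng(seed)
    pops = [f"C{i + 1}" for i in range(n_populations)]
    temperature = rng.normal(t_mean, t_sd, size=n_populations)
    openings = rng.integers(o_lo, o_hi + 1, size=n_populations)
    distance = rng.uniform(d_lo, d_hi, size=n_populations)
    # two clusters of caves on the lake's western shore
    n_h = int(np.ceil(n_populations * 15 / 24)) if n_populations > 1 else 1
    centers = {"H": (65.585, -17.056), "V": (65.617, -17.070)}
    areas = ["H"] * n_h + ["V"] * (n_populations - n_h)
    lat = np.array([centers[a][0] for a in areas]) + rng.normal(0, 0.004, n_populations)
    lon = np.array([centers[a][1] for a in areas]) + rng.normal(0, 0.004, n_populations)
    df = pd.DataFrame({
        "temperature": temperature,
        "openings": openings.astype(int),
        "distance": distance,
        "area": areas,
        "lat": lat,
        "lon": lon,
    }, index=pd.Index(pops, name="population"))
    constant = [c for c in ("temperature", "openings", "distance")
                if np.ptp(df[c].to_numpy(dtype=float)) == 0]
    df.attrs["constant_columns"] = constant
    return df


# ---------------------------------------------------------------------------
# phenotypes

def _standardize_cols(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - x.mean(axis=0)) / sd


def trait_params_for_proportions(E: float, G: float, O: float, env: pd.DataFrame,
                                 sigma_t: float = 1.0, var_resid: float = 1.0,
                                 **extra) -> TraitParams:
    """Trait parameters whose true partition is exactly (E, G, O).

    Loads the whole environmental share on the temperature coefficient:
    ``beta_T`` is chosen so that ``beta' cov(env_std) beta = E * sigma_t``
    for the given environment table (standardized covariates, populations
    weighted equally, ddof = 1).
    """
    if not np.isclose(E + G + O, 1.0):
        raise ValueError("E + G + O must sum to 1")
    n = len(env)
    t_std = _standardize_cols(env[["temperature"]].to_numpy(dtype=float))[:, 0]
    var_t = t_std.var(ddof=1)
    beta_t = np.sqrt(E * sigma_t / var_t) if E > 0 else 0.0
    return TraitParams(beta_T=beta_t, var_gen=G * sigma_t, var_cave=O * sigma_t,
                       var_resid=var_resid, **extra)


def simulate_phenotypes(truth: SimulationTruth, env: pd.DataFrame, n_per_pop,
                        trait_params: TraitParams, seed=None,
                        fl_mean: float = 75.0, fl_sd: float = 15.0) -> pd.DataFrame:
    """Individual trait values under the random-regression model.

    ``z_ij = alpha + beta_L L + beta_T T + beta_O O + beta_D D + delta terms
    + g_a + g_b L + c_a + c_b L + e`` with the ``g`` effects drawn jointly
    with covariance ``var_gen * S`` (S from the recorded truth), ``c``
    effects independent, covariates standardized before use.  Fork lengths
    are Normal(``fl_mean``, ``fl_sd``) mm; ``L`` is their standardized value.
    The realized true partition is recorded in ``truth.proportions``.
    """
    pops = list(env.index.astype(str))
    S = truth.similarity.values if truth.similarity is not None else np.eye(len(pops))
    sim_labels = truth.similarity.labels if truth.similarity is not None else pops
    order = [sim_labels.index(p) for p in pops]
    S = S[np.ix_(order, order)]
    if trait_params.var_gen > 0 and np.allclose(S, np.eye(len(pops))):
        warnings.warn("S is the identity: G and O components are confounded")
    w = np.linalg.eigvalsh((S + S.T) / 2)
    if w.min() < -1e-8:
        raise ValueError("similarity matrix is not PSD after repair")
    if isinstance(n_per_pop, int):
        n_per_pop = [n_per_pop] * len(pops)
    rng = np.random.default_rng(seed)
    env_std = _standardize_cols(env[["temperature", "openings", "distance"]].to_numpy(dtype=float))
    wv, vv = np.linalg.eigh((S + S.T) / 2)
    s_half = (vv * np.sqrt(np.maximum(wv, 0))) @ vv.T
    tp = trait_params
    g_a = s_half @ rng.standard_normal(len(pops)) * np.sqrt(tp.var_gen)
    g_b = s_half @ rng.standard_normal(len(pops)) * np.sqrt(tp.var_gen_slope)
    c_a = rng.standard_normal(len(pops)) * np.sqrt(tp.var_cave)
    c_b = rng.standard_normal(len(pops)) * np.sqrt(tp.var_cave_slope)
    rows = []
    fls = []
    for j, (pop, n) in enumerate(zip(pops, n_per_pop)):
        fl = rng.normal(fl_mean, fl_sd, size=n)
        fls.append(fl)
        rows.extend((pop, j) for _ in range(n))
    fl_all = np.concatenate(fls)
    L = (fl_all - fl_all.mean()) / fl_all.std(ddof=0)
    j_idx = np.array([j for _, j in rows])
    T, O, Dv = env_std[j_idx, 0], env_std[j_idx, 1], env_std[j_idx, 2]
    e = rng.standard_normal(len(rows)) * np.sqrt(tp.var_resid)
    z = (tp.alpha + tp.beta_L * L + tp.beta_T * T + tp.beta_O * O + tp.beta_D * Dv
         + tp.delta_T * T * L + tp.delta_O * O * L + tp.delta_D * Dv * L
         + g_a[j_idx] + g_b[j_idx] * L + c_a[j_idx] + c_b[j_idx] * L + e)
    df = pd.DataFrame({
        "individual": [f"{pops[j]}_p{k}" for k, j in enumerate(j_idx)],
        "population": [pops[j] for j in j_idx],
        "fork_length": fl_all,
        "trait": z,
    })
    beta_env = np.array([tp.beta_T, tp.beta_O, tp.beta_D])
    var_env = env_variance(beta_env, env_std)
    sigma_t = var_env + tp.var_gen + tp.var_cave
    if sigma_t > 0:
        E = var_env / sigma_t
        G = tp.var_gen / sigma_t
        O_prop = 1.0 - E - G
    else:
        E = G = O_prop = np.nan
    truth.cave_effects = {"g_a": g_a, "g_b": g_b, "c_a": c_a, "c_b": c_b}
    truth.proportions = {"E": E, "G": G, "O": O_prop}
    truth.variance_components = {
        "var_env": var_env, "var_gen": tp.var_gen, "var_cave": tp.var_cave,
        "var_resid": tp.var_resid, "sigma_t": sigma_t,
    }
    return df


# ---------------------------------------------------------------------------
# landmarks

_TEMPLATE = np.array([
    (0.00, 0.010),    # 0 snout tip
    (0.08, 0.060),    # 1 mid-head dorsal (sliding)
    (0.18, 0.090),    # 2 nape
    (0.27, 0.110),    # 3 pre-dorsal outline (sliding)
    (0.36, 0.120),    # 4 dorsal-fin anterior insertion
    (0.50, 0.100),    # 5 dorsal-fin posterior insertion
    (0.70, 0.070),    # 6 adipose-fin insertion
    (0.86, 0.045),    # 7 caudal-peduncle dorsal (sliding)
    (0.93, 0.035),    # 8 upper caudal-fin base
    (1.00, 0.000),    # 9 fork of the caudal fin
    (0.93, -0.035),   # 10 lower caudal-fin base
    (0.86, -0.045),   # 11 caudal-peduncle ventral (sliding)
    (0.73, -0.060),   # 12 anal-fin posterior insertion
    (0.63, -0.085),   # 13 anal-fin anterior insertion
    (0.52, -0.100),   # 14 mid-belly (sliding)
    (0.42, -0.105),   # 15 pelvic-fin insertion
    (0.22, -0.085),   # 16 pectoral-fin insertion
    (0.10, -0.055),   # 17 ventral head (sliding)
    (0.02, -0.020),   # 18 lower jaw tip
    (0.07, -0.005),   # 19 posterior end of the maxilla
    (0.10, 0.025),    # 20 eye centre
])
_SLIDING = [1, 3, 7, 11, 14, 17]
_CHAINS = [(0, 1, 2), (2, 3, 4), (6, 7, 8), (10, 11, 12), (13, 14, 15), (16, 17, 18)]
#: head landmarks: snout, dorsal head outline, nape, pectoral, ventral head,
#: jaw, maxilla, eye
_HEAD_SUBSET = [0, 1, 2, 16, 17, 18, 19, 20]


def default_template() -> np.ndarray:
    """Unit-centroid-size 21-landmark fish template (centred)."""
    t = _TEMPLATE - _TEMPLATE.mean(axis=0)
    return t / np.sqrt(np.sum(t**2))


def _nuisance_directions(template: np.ndarray) -> np.ndarray:
    """Orthonormal basis of similarity-transform directions at the template."""
    k = template.shape[0]
    tx = np.tile([1.0, 0.0], (k, 1))
    ty = np.tile([0.0, 1.0], (k, 1))
    rot = np.column_stack([-template[:, 1], template[:, 0]])
    scale = template.copy()
    dirs = np.stack([d.ravel() for d in (tx, ty, rot, scale)])
    q, _ = np.linalg.qr(dirs.T)
    return q.T


def default_deformation_basis(template: np.ndarray | None = None) -> np.ndarray:
    """Two orthonormal shape-deformation axes, orthogonal to similarity moves.

    Axis 1 deepens the body and enlarges the head (the trait axis); axis 2
    elongates and slims the body (the allometric axis).  Both are
    Gram–Schmidt orthogonalized against translation, rotation and scaling at
    the template and against each other.
    """
    t = default_template() if template is None else template
    head = t[:, 0] < np.quantile(t[:, 0], 0.3)
    raw1 = np.zeros_like(t)
    raw1[:, 1] = t[:, 1] * 1.0            # depth change
    raw1[head, 0] -= 0.03                 # head elongation forward
    raw2 = np.zeros_like(t)
    raw2[:, 0] = t[:, 0] - t[:, 0].mean()
    raw2[:, 1] = -0.5 * t[:, 1]
    nuis = _nuisance_directions(t)
    basis = []
    for raw in (raw1, raw2):
        v = raw.ravel().astype(float)
        v = v - nuis.T @ (nuis @ v)
        for b in basis:
            v = v - b * (b @ v)
        norm = np.linalg.norm(v)
        if norm < 1e-10:
            raise ValueError("deformation direction degenerate after orthogonalization")
        basis.append(v / norm)
    return np.stack(basis)


def simulate_landmarks(phenotypes: pd.DataFrame, template: np.ndarray | None = None,
                       basis: np.ndarray | None = None, noise_sd: float = 0.01,
                       seed=None, trait_scale: float = 0.05,
                       allometry_scale: float = 0.03) -> LandmarkSet:
    """Landmark configurations encoding the trait and an allometric axis.

    Each specimen is ``template + trait_std * trait_scale * basis1 +
    FL_std * allometry_scale * basis2 + isotropic Gaussian noise``, then
    randomly rotated, translated and scaled.  The basis must be orthonormal
    and orthogonal to the template's similarity-transform directions, so the
    trait is recoverable by GPA + PCA up to sign.
    """
    t = default_template() if template is None else np.asarray(template, dtype=float)
    basis = default_deformation_basis(t) if basis is None else np.asarray(basis, dtype=float)
    gram = basis @ basis.T
    if not np.allclose(gram, np.eye(basis.shape[0]), atol=1e-8):
        raise ValueError("deformation basis is not orthonormal")
    nuis = _nuisance_directions(t)
    if not np.allclose(nuis @ basis.T, 0.0, atol=1e-8):
        raise ValueError("deformation basis is not orthogonal to similarity transforms")
    rng = np.random.default_rng(seed)
    k = t.shape[0]
    trait = phenotypes["trait"].to_numpy(dtype=float)
    fl = phenotypes["fork_length"].to_numpy(dtype=float)
    trait_std = (trait - trait.mean()) / (trait.std(ddof=0) or 1.0)
    fl_std = (fl - fl.mean()) / (fl.std(ddof=0) or 1.0)
    coords = np.zeros((len(phenotypes), k, 2))
    for i in range(len(phenotypes)):
        shape = (t.ravel()
                 + trait_std[i] * trait_scale * basis[0]
                 + fl_std[i] * allometry_scale * basis[1]
                 + rng.normal(0, noise_sd, size=2 * k)).reshape(k, 2)
        angle = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(angle), -np.sin(angle)],
                        [np.sin(angle), np.cos(angle)]])
        scale = rng.uniform(0.5, 2.0)
        shift = rng.uniform(-1, 1, size=2)
        coords[i] = scale * shape @ rot.T + shift
    return LandmarkSet(
        coords=coords,
        specimen_ids=phenotypes["individual"].to_numpy(),
        populations=phenotypes["population"].to_numpy(),
        fork_length=fl,
        sliding=list(_SLIDING),
        chains=list(_CHAINS),
        head_subset=list(_HEAD_SUBSET),
    )


# ---------------------------------------------------------------------------
# capture histories

def simulate_capture_histories(true_sizes: dict, capture_prob: float,
                               movement_pairs=(), seed=None) -> pd.DataFrame:
    """Two-session capture histories with optional inter-cave movers.

    Session 1 captures are marked; session 2 captures of marked fish are
    recorded as recaptures.  ``movement_pairs`` is a list of
    ``(from_pop, to_pop, n_movers)``: the movers reside in ``from_pop`` in
    session 1 and in ``to_pop`` in session 2.
    """
    if not (0 < capture_prob <= 1):
        raise ValueError("capture_prob must be in (0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    pops = list(true_sizes)
    residence2 = {}
    tags = {}
    for pop in pops:
        n = int(true_sizes[pop])
        ids = [f"{pop}_f{k + 1}" for k in range(n)]
        tags[pop] = ids
        for t in ids:
            residence2[t] = pop
    for src, dst, n_move in movement_pairs:
        if src not in true_sizes or dst not in true_sizes:
            raise ValueError(f"movement pair ({src}, {dst}) references unknown population")
        movers = rng.choice(tags[src], size=n_move, replace=False)
        for t in movers:
            residence2[t] = dst
    marked = set()
    for pop in pops:
        for t in tags[pop]:
            if rng.random() < capture_prob:
                rows.append({"tag_id": t, "population": pop, "session": 1,
                             "event": "first-capture"})
                marked.add(t)
    for t, pop in residence2.items():
        if rng.random() < capture_prob:
            rows.append({"tag_id": t, "population": pop, "session": 2,
                         "event": "recapture" if t in marked else "first-capture"})
    return pd.DataFrame(rows, columns=["tag_id", "population", "session", "event"])


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class SyntheticStudy:
    genotypes: GenotypeTable
    environment: pd.DataFrame
    phenotypes: pd.DataFrame
    landmarks: LandmarkSet
    captures: pd.DataFrame
    truth: SimulationTruth
    config: SimulationConfig


def simulate_study(config: SimulationConfig | None = None, seed=None) -> SyntheticStudy:
    """Run every generator stage with independent child seed streams."""
    config = config or default_config()
    root = np.random.SeedSequence(seed if seed is not None else config.seed)
    children = root.spawn(6)
    stage_seeds = {name: f"{child.entropy}:{child.spawn_key}" for name, child in zip(
        ("source", "colonization", "environment", "phenotypes", "landmarks", "captures"),
        children)}
    source = simulate_source_frequencies(config.loci, np.random.default_rng(children[0]))
    gt, truth = simulate_colonization(source, config, np.random.default_rng(children[1]))
    env = simulate_environment(config.n_populations, config.env_ranges,
                               np.random.default_rng(children[2]))
    phen = simulate_phenotypes(truth, env, config.individuals_per_pop_phenotype,
                               config.trait_params, np.random.default_rng(children[3]))
    lms = simulate_landmarks(phen, seed=np.random.default_rng(children[4]))
    sizes = truth.census_sizes
    movers = [(a, b, min(m, sizes[a])) for a, b, m in config.migration_pairs if m > 0]
    captures = simulate_capture_histories(sizes, config.capture_prob,
                                          movement_pairs=movers,
                                          seed=np.random.default_rng(children[5]))
    truth.stage_seeds = stage_seeds
    return SyntheticStudy(genotypes=gt, environment=env, phenotypes=phen,
                          landmarks=lms, captures=captures, truth=truth, config=config)


def write_study(study: SyntheticStudy, outdir) -> None:
    """Write a generated study to disk (GENEPOP, TPS, CSVs, JSON truth)."""
    from .io import write_genepop, write_tps

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_genepop(study.genotypes, out / "genotypes.gen", title="synthetic cave study")
    write_tps(study.landmarks, out / "landmarks.tps")
    study.environment.to_csv(out / "environment.csv")
    study.phenotypes.to_csv(out / "phenotypes.csv", index=False)
    study.captures.to_csv(out / "captures.csv", index=False)
    truth = study.truth
    payload = {
        "source_frequencies": [f.tolist() for f in truth.source_frequencies],
        "census_sizes": truth.census_sizes,
        "migrants": [list(m) for m in (truth.migrants or [])],
        "proportions": truth.proportions,
        "variance_components": truth.variance_components,
        "similarity": {
            "labels": truth.similarity.labels,
            "values": truth.similarity.values.tolist(),
        } if truth.similarity is not None else None,
        "stage_seeds": {k: str(v) for k, v in truth.stage_seeds.items()},
        "config": {
            **{k: v for k, v in asdict(study.config).items()
               if k not in ("loci", "trait_params")},
            "loci": [asdict(l) for l in study.config.loci],
            "trait_params": asdict(study.config.trait_params),
        },
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=2, default=str))
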
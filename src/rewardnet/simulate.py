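"""Synthetic cohort generator.

Emulates the statistical structure the downstream analyses assume, so the
whole pipeline is testable without subject data: two groups (heroin
abusers HA, healthy controls HC) with group-specific age and smoking
covariates; Hardy-Weinberg genotypes at configurable minor-allele
frequencies with haplotype-level LD blocks; per-edge streamline and FA
voxel maps on a shared grid, with a group deficit and an additive genotype
effect planted on a configurable subset of the 276 edges; and cognition
(MoCA) generated as a linear function of network strength so that the
genotype -> network -> cognition indirect path has a known product a*b.

Every draw comes from one seeded generator: the same config and seed
reproduce the cohort bit for bit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import NodeAtlas, default_atlas, edge_label
from .connectome import EdgeVoxelData
from .popgen import MISSING, SNP, GenotypeTable

GROUPS = ("HA", "HC")


@dataclass(frozen=True)
class SNPSpec:
    """One simulated biallelic marker: ``maf`` is the minor-allele frequency."""

    snp_id: str
    maf: float
    major_allele: str = "A"
    minor_allele: str = "G"
    risk_allele: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.maf < 1:
            raise ValueError(f"{self.snp_id}: MAF must be in (0, 1), got {self.maf}")
        if self.major_allele == self.minor_allele:
            raise ValueError(f"{self.snp_id}: alleles must differ")
        if not self.risk_allele:
            object.__setattr__(self, "risk_allele", self.minor_allele)


@dataclass(frozen=True)
class LDBlock:
    """SNPs generated as a haplotype chain with adjacent correlation ``r``."""

    snp_ids: tuple[str, ...]
    r: float

    def __post_init__(self) -> None:
        if not 0 <= self.r <= 1:
            raise ValueError(f"LD correlation must be in [0, 1], got {self.r}")
        if len(self.snp_ids) < 2:
            raise ValueError("LD block needs at least two SNPs")


@dataclass(frozen=True)
class GeneticEffect:
    """Additive genotype effect on affected-edge strength, in SD units.

    The per-allele slope in controls is ``beta``; in cases it is
    ``beta + interaction`` (a gene x addiction interaction).
    """

    snp_id: str
    beta: float
    interaction: float = 0.0


@dataclass(frozen=True)
class MediationParams:
    """Generative model for MoCA given dosage and Diff-edge strength."""

    b: float = 120.0          # MoCA points per unit of mean Diff strength
    c_prime: float = -0.3     # direct dosage effect, MoCA points per allele
    noise_sd: float = 2.0
    intercept: float = -29.0  # offsets b * baseline strength to the MoCA scale
    group_shift: float = -2.0  # extra HA deficit not through the network
    age_beta: float = -0.05
    cigs_beta: float = 0.0


@dataclass(frozen=True)
class CovariateGroupModel:
    age_mean: float
    age_sd: float
    cigs_mean: float
    cigs_sd: float


#: Group-specific covariate distributions (years; cigarettes/day).
DEFAULT_COVARIATES: dict[str, CovariateGroupModel] = {
    "HA": CovariateGroupModel(36.2, 3.9, 26.0, 9.1),
    "HC": CovariateGroupModel(37.5, 5.0, 8.7, 9.8),
}


@dataclass
class SimulationConfig:
    n_per_group: int = 40
    grid_shape: tuple[int, int, int] = (14, 14, 14)
    region_shape: tuple[int, int, int] = (2, 2, 2)
    atlas: NodeAtlas = field(default_factory=default_atlas)
    snp_specs: list[SNPSpec] = field(
        default_factory=lambda: [SNPSpec("rs279858", maf=0.45)]
    )
    ld_blocks: list[LDBlock] = field(default_factory=list)
    affected_edges: dict[tuple[str, str], float] | None = None
    genetic_effect: GeneticEffect | None = field(
        default_factory=lambda: GeneticEffect("rs279858", beta=-1.0, interaction=1.0)
    )
    mediation: MediationParams = field(default_factory=MediationParams)
    covariate_model: dict[str, CovariateGroupModel] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )
    fa_baseline: float = 0.5
    edge_noise_sd: float = 0.03   # SD unit for standardized planted effects
    voxel_noise_sd: float = 0.01
    streamline_mean: float = 5.0
    streamline_sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        known = {s.snp_id for s in self.snp_specs}
        for block in self.ld_blocks:
            unknown = set(block.snp_ids) - known
            if unknown:
                raise ValueError(f"LD block names unknown SNPs {sorted(unknown)}")
        if self.genetic_effect is not None and self.genetic_effect.snp_id not in known:
            raise ValueError(
                f"genetic effect names unknown SNP {self.genetic_effect.snp_id!r}"
            )
        if self.affected_edges is None:
            self.affected_edges = default_affected_edges(self.atlas)
        edges = set(self.atlas.edges())
        canon = {}
        for e, eff in self.affected_edges.items():
            e = self.atlas.canonical_edge(*e)
            if e not in edges:
                raise ValueError(f"affected edge {edge_label(e)} not in atlas")
            canon[e] = float(eff)
        self.affected_edges = canon
        n_slots = 1
        for dim, r in zip(self.grid_shape, self.region_shape):
            if r > dim:
                raise ValueError("region shape exceeds grid")
            n_slots *= dim // r
        if n_slots < len(edges):
            raise ValueError(
                f"grid {self.grid_shape} holds {n_slots} disjoint "
                f"{self.region_shape} regions; need {len(edges)}"
            )


def default_affected_edges(
    atlas: NodeAtlas, effect: float = -2.5, n_edges: int = 10
) -> dict[tuple[str, str], float]:
    """Default planted deficit: the first VTA-linked edges at ``effect`` SD."""
    vta_edges = [
        e for e in atlas.edges() if "VTA" in (e[0].split("_")[0], e[1].split("_")[0])
    ]
    return {e: effect for e in vta_edges[:n_edges]}


@dataclass
class Truth:
    """Record of the planted effects, for recovery tests."""

    affected_edges: dict[tuple[str, str], float]
    genetic_effect: GeneticEffect | None
    mediation: MediationParams
    region_origins: dict[tuple[str, str], tuple[int, int, int]]
    region_shape: tuple[int, int, int]
    edge_noise_sd: float
    true_diff_mean: pd.Series | None = None  # planted mean strength per subject

    @property
    def indirect_effect(self) -> float:
        """Planted a*b in the control group (MoCA points per risk allele)."""
        if self.genetic_effect is None:
            return 0.0
        a = self.genetic_effect.beta * self.edge_noise_sd
        return a * self.mediation.b


@dataclass
class CohortBundle:
    subjects: pd.DataFrame
    genotypes: GenotypeTable
    voxel_data: dict[tuple[str, str], EdgeVoxelData]
    truth: Truth


def _haplotype_block(
    n_hap: int, specs: list[SNPSpec], r: float, rng: np.random.Generator
) -> np.ndarray:
    """Minor-allele indicators for one LD block, as a Markov haplotype chain.

    Adjacent SNPs share haplotype disequilibrium D = r * sqrt(p1 q1 p2 q2),
    i.e. haplotype correlation exactly ``r`` for each adjacent pair;
    correlation between distant SNPs decays multiplicatively.
    """
    H = np.zeros((n_hap, len(specs)), dtype=np.int8)
    H[:, 0] = rng.random(n_hap) < specs[0].maf
    for k in range(1, len(specs)):
        p1, p2 = specs[k - 1].maf, specs[k].maf
        d = r * np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
        f11 = p1 * p2 + d
        if f11 > min(p1, p2) + 1e-12 or p2 - f11 > (1 - p1) + 1e-12:
            raise ValueError(
                f"LD correlation {r} infeasible for MAFs {p1}, {p2}"
            )
        p_given1 = f11 / p1
        p_given0 = (p2 - f11) / (1 - p1)
        u = rng.random(n_hap)
        prev = H[:, k - 1] == 1
        H[:, k] = np.where(prev, u < p_given1, u < p_given0)
    return H


def simulate_genotypes(
    n: int,
    snp_specs: list[SNPSpec],
    ld_blocks: list[LDBlock] | None = None,
    seed: int | np.random.Generator = 0,
    missing_rate: float = 0.0,
    subject_ids: list[str] | None = None,
) -> GenotypeTable:
    """HWE genotypes with haplotype-level LD blocks.

    Two haplotypes per subject are drawn independently from the block's
    haplotype distribution, so Hardy-Weinberg proportions hold at every SNP
    by construction; SNPs outside any block are independent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ld_blocks = ld_blocks or []
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spec_by_id = {s.snp_id: s for s in snp_specs}
    if len(spec_by_id) != len(snp_specs):
        raise ValueError("duplicate SNP ids in specs")
    in_block: set[str] = set()
    for block in ld_blocks:
        dup = in_block & set(block.snp_ids)
        if dup:
            raise ValueError(f"SNPs {sorted(dup)} appear in multiple LD blocks")
        in_block |= set(block.snp_ids)

    minor = pd.DataFrame(index=range(n), columns=[s.snp_id for s in snp_specs],
                         dtype=int)
    # draw in declared SNP order for a stable random stream
    done: set[str] = set()
    for spec in snp_specs:
        if spec.snp_id in done:
            continue
        block = next((b for b in ld_blocks if spec.snp_id in b.snp_ids), None)
        if block is None:
            h = rng.random((n, 2)) < spec.maf
            minor[spec.snp_id] = h.sum(axis=1)
            done.add(spec.snp_id)
        else:
            bspecs = [spec_by_id[sid] for sid in block.snp_ids]
            H = _haplotype_block(2 * n, bspecs, block.r, rng)
            dose = H[0::2] + H[1::2]
            for j, sid in enumerate(block.snp_ids):
                minor[sid] = dose[:, j]
                done.add(sid)

    if subject_ids is None:
        subject_ids = [f"S{i:04d}" for i in range(n)]
    calls = {}
    for spec in snp_specs:
        d = minor[spec.snp_id].to_numpy()
        geno = np.array([
            spec.major_allele * 2,
            spec.major_allele + spec.minor_allele,
            spec.minor_allele * 2,
        ])[d]
        if missing_rate > 0:
            geno = np.where(rng.random(n) < missing_rate, MISSING, geno)
        calls[spec.snp_id] = geno
    snps = [
        SNP(s.snp_id, allele_a=s.major_allele, allele_b=s.minor_allele,
            risk_allele=s.risk_allele)
        for s in snp_specs
    ]
    return GenotypeTable(
        subjects=list(subject_ids), snps=snps,
        calls=pd.DataFrame(calls, index=subject_ids),
    )


def simulate_covariates(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Subject table with group, age and cigarettes/day (group-specific)."""
    rows = []
    for group in GROUPS:
        mdl = config.covariate_model[group]
        for k in range(config.n_per_group):
            rows.append({
                "subject": f"{group}{k:03d}", "group": group,
                "age": rng.normal(mdl.age_mean, mdl.age_sd),
                "cigarettes_per_day": max(
                    0.0, round(rng.normal(mdl.cigs_mean, mdl.cigs_sd))
                ),
            })
    return pd.DataFrame(rows).set_index("subject")


def _region_origins(
    config: SimulationConfig,
) -> dict[tuple[str, str], tuple[int, int, int]]:
    """Deterministic disjoint lattice placement of one region per edge."""
    steps = [
        range(0, dim - r + 1, r)
        for dim, r in zip(config.grid_shape, config.region_shape)
    ]
    slots = list(itertools.product(*steps))
    edges = config.atlas.edges()
    return {e: slots[i] for i, e in enumerate(edges)}


def simulate_voxel_data(
    config: SimulationConfig,
    subjects: pd.DataFrame,
    dosage: pd.Series,
    rng: np.random.Generator,
    region_origins: dict[tuple[str, str], tuple[int, int, int]] | None = None,
) -> tuple[dict[tuple[str, str], EdgeVoxelData], dict, pd.Series]:
    """Per-edge streamline maps and shared FA maps with planted effects.

    Each edge owns a disjoint contiguous voxel region.  Within it the
    streamline value is positive for every subject and the FA value is

        baseline + sd * (effect_e * 1[HA]
                         + (beta + inter * 1[HA]) * (dose - 2 * maf))
                 + subject-edge noise + small voxel noise,

    clipped to [0, 1]; outside all regions the streamline value is exactly
    zero and FA is baseline + voxel noise.  The dosage term is centered at
    its expected value so the genotype effect does not shift group means:
    the group contrast stays exactly ``effect_e`` SD while the per-allele
    slope (the mediation a path) is untouched.  Returns the voxel data,
    the region truth, and the per-subject planted mean strength over the
    affected (Diff) edges.
    """
    if region_origins is None:
        region_origins = _region_origins(config)
    occupied = np.zeros(config.grid_shape, dtype=bool)
    slices = {}
    for e, origin in region_origins.items():
        sl = tuple(
            slice(o, o + r) for o, r in zip(origin, config.region_shape)
        )
        if occupied[sl].any():
            raise ValueError(
                f"planted region for edge {edge_label(e)} overlaps another edge"
            )
        occupied[sl] = True
        slices[e] = sl

    subj_ids = list(subjects.index)
    n = len(subj_ids)
    is_case = (subjects["group"] == "HA").to_numpy(dtype=float)
    dose = dosage.loc[subj_ids].to_numpy(dtype=float)
    sd = config.edge_noise_sd
    ge = config.genetic_effect
    if ge is not None:
        spec = next(s for s in config.snp_specs if s.snp_id == ge.snp_id)
        expected_dose = 2 * spec.maf if spec.risk_allele == spec.minor_allele \
            else 2 * (1 - spec.maf)
        dose = dose - expected_dose

    fa = rng.normal(config.fa_baseline, config.voxel_noise_sd,
                    size=(n, *config.grid_shape)).astype(np.float32)
    region_nvox = int(np.prod(config.region_shape))
    voxel_data: dict[tuple[str, str], EdgeVoxelData] = {}
    diff_signal = np.zeros(n)
    edges = config.atlas.edges()
    streamlines = {}
    for e in edges:
        sl = slices[e]
        effect = config.affected_edges.get(e, 0.0)
        signal = np.full(n, config.fa_baseline)
        signal += sd * effect * is_case
        if ge is not None and effect != 0.0:
            signal += sd * (ge.beta + ge.interaction * is_case) * dose
        signal += rng.normal(0.0, sd, size=n)
        vox = signal[:, None] + rng.normal(
            0.0, config.voxel_noise_sd, size=(n, region_nvox)
        )
        fa[(slice(None), *sl)] = vox.reshape(n, *config.region_shape)
        if e in config.affected_edges:
            diff_signal += signal
        stream = np.zeros((n, *config.grid_shape), dtype=np.float32)
        stream[(slice(None), *sl)] = np.abs(rng.normal(
            config.streamline_mean, config.streamline_sd, size=(n, region_nvox)
        )).reshape(n, *config.region_shape)
        streamlines[e] = stream
    np.clip(fa, 0.0, 1.0, out=fa)
    for e in edges:
        voxel_data[e] = EdgeVoxelData(
            edge=e, subjects=subj_ids, streamline=streamlines[e], fa=fa
        )
    n_diff = max(len(config.affected_edges), 1)
    true_diff_mean = pd.Series(diff_signal / n_diff, index=subj_ids)
    truth_regions = {e: region_origins[e] for e in edges}
    return voxel_data, truth_regions, true_diff_mean


def simulate_phenotypes(
    subjects: pd.DataFrame,
    diff_mean: pd.Series,
    dosage: pd.Series,
    params: MediationParams,
    rng: np.random.Generator,
) -> pd.Series:
    """MoCA as a linear mediated function of network strength.

    The indirect (a) path is realized upstream through the genotype effect
    on edge FA; here cognition adds the direct path c', the mediator slope
    b, covariate terms and Gaussian noise.
    """
    idx = subjects.index
    is_case = (subjects["group"] == "HA").to_numpy(dtype=float)
    moca = (
        params.intercept
        + params.group_shift * is_case
        + params.c_prime * dosage.loc[idx].to_numpy(dtype=float)
        + params.b * diff_mean.loc[idx].to_numpy(dtype=float)
        + params.age_beta * subjects["age"].to_numpy()
        + params.cigs_beta * subjects["cigarettes_per_day"].to_numpy()
        + rng.normal(0.0, params.noise_sd, size=len(idx))
    )
    return pd.Series(moca, index=idx, name="MoCA")


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Generate a full synthetic cohort from one seeded stream."""
    rng = np.random.default_rng(config.seed)
    subjects = simulate_covariates(config, rng)
    genotypes = simulate_genotypes(
        n=len(subjects), snp_specs=config.snp_specs,
        ld_blocks=config.ld_blocks, seed=rng,
        missing_rate=config.missing_rate, subject_ids=list(subjects.index),
    )
    if config.genetic_effect is not None:
        dosage = genotypes.dosage(config.genetic_effect.snp_id).fillna(0.0)
    else:
        dosage = pd.Series(0.0, index=subjects.index)
    voxel_data, regions, true_diff = simulate_voxel_data(
        config, subjects, dosage, rng
    )
    subjects = subjects.copy()
    subjects["MoCA"] = simulate_phenotypes(
        subjects, true_diff, dosage, config.mediation, rng
    )
    truth = Truth(
        affected_edges=dict(config.affected_edges),
        genetic_effect=config.genetic_effect,
        mediation=config.mediation,
        region_origins=regions,
        region_shape=config.region_shape,
        edge_noise_sd=config.edge_noise_sd,
        true_diff_mean=true_diff,
    )
    return CohortBundle(
        subjects=subjects, genotypes=genotypes,
        voxel_data=voxel_data, truth=truth,
    )
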
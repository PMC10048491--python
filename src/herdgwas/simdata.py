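"""Structured-population genotype and milk-trait simulator.

The generator emulates a small dairy herd of the kind the pipeline targets: a
few thousand cows kept on a handful of farms, descended from a few dozen
sires (deep half-sib families), born over roughly a decade, genotyped at
1e4-1e6 biallelic variants with block-wise linkage disequilibrium and an
SNP-array-like MAF spectrum. Defaults mirror that design: 2000 cows, 37
sires, 8 farms, 10 birth years.

Genotypes come from a haplotype-copying (mosaic) model: each chromosome is
cut into LD blocks with exponentially distributed lengths; every gamete picks
one haplotype from a small founder pool per block. Within a block the
founder alleles are laid out as nested carrier sets along a per-block
founder ordering (a star-genealogy pattern: D' near 1 and substantial r2
between block neighbours, as in a low-Ne livestock population), with a
configurable fraction of "recombinant" variants whose carrier set is
re-drawn independently. Across blocks founder picks are independent, so r2
decays to ~0 beyond the block span.
Sires are represented by two founder-index gametes each, so paternal
half-sibs share elevated identity-by-state. Optional discrete subpopulations
with Balding-Nichols allele-frequency divergence provide stratification for
confounding experiments.

Phenotypes follow the additive fixed-effects trait model used by the
association stage: trait value = farm/year/season covariate effects +
planted QTL effects x dosage + a marker-based polygenic term + Gaussian
noise, with the noise rescaled so the realized narrow-sense heritability
equals the configured h2 exactly. Milk yield (kg) and fat/protein content
(%) are simulated per lactation; fat/protein yields are their products, so
yield traits are strongly correlated within a lactation while the two
content traits stay nearly independent — the correlation structure typical
of 305-day milk recording data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

SIM_TRAITS = ("milk_kg", "fat_pct", "protein_pct")
#: traits reported downstream (yields derived from contents at record level)
ALL_TRAITS = ("milk_kg", "fat_kg", "protein_kg", "fat_pct", "protein_pct")


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class QTLSpec:
    """A planted causal variant: position, target trait and allele effect.

    ``effect`` is the allele-substitution effect per copy of the alternate
    allele in trait units (kg for milk yield, percentage points for
    contents). ``maf`` controls the founder-pool allele frequency.
    """

    chrom: str
    pos: int
    trait: str
    effect: float
    maf: float = 0.3


def _default_h2() -> dict:
    # mid-range single-lactation heritabilities for yield and content traits
    return {"milk_kg": 0.40, "fat_pct": 0.50, "protein_pct": 0.60}


def _default_means() -> dict:
    return {"milk_kg": 6500.0, "fat_pct": 4.3, "protein_pct": 3.7}


def _default_sds() -> dict:
    return {"milk_kg": 800.0, "fat_pct": 0.35, "protein_pct": 0.25}


def _default_covariate_effects() -> dict:
    # magnitudes in trait-SD units (per level for categoricals, per day for
    # age at first calving)
    return {
        "farm": 0.5,
        "sire": 0.0,
        "birth_year": 0.25,
        "birth_season": 0.15,
        "calving_year": 0.15,
        "calving_season": 0.10,
        "age_first_calving": 0.001,
    }


@dataclass
class SimConfig:
    """Study-design parameters for one simulated herd."""

    n_individuals: int = 2000
    n_sires: int = 37
    n_dams: int = 0  # 0 -> every cow has a unique (unobserved) dam
    n_farms: int = 8
    birth_years: int = 10
    first_birth_year: int = 2007
    n_chromosomes: int = 3
    variants_per_chromosome: int = 2000
    chromosome_length_bp: int = 100_000_000
    include_x: bool = False  # adds an extra ordinary diploid chromosome "X"
    ld_block_mean_kb: float = 100.0
    ld_noise: float = 0.3  # fraction of variants with a re-drawn carrier set
    n_founder_haplotypes: int = 20
    maf_range: tuple = (0.05, 0.5)
    rare_tail_fraction: float = 0.05
    rare_maf_range: tuple = (0.01, 0.05)
    missing_rate: float = 0.0
    n_subpops: int = 1
    fst: float = 0.0
    confound_sd: float = 0.0  # subpop phenotype shift, trait-SD units
    qtl: tuple = ()
    h2: dict = field(default_factory=_default_h2)
    n_polygenic: int = 1000
    trait_mean: dict = field(default_factory=_default_means)
    trait_sd: dict = field(default_factory=_default_sds)
    lactation_scale: tuple = (1.0, 1.08, 1.12)
    lactation_retention: tuple = (0.95, 0.82, 0.80)  # conditional on previous
    short_lactation_rate: float = 0.05
    covariate_effects: dict = field(default_factory=_default_covariate_effects)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_individuals": self.n_individuals,
            "n_sires": self.n_sires,
            "n_farms": self.n_farms,
            "birth_years": self.birth_years,
            "n_chromosomes": self.n_chromosomes,
            "variants_per_chromosome": self.variants_per_chromosome,
            "chromosome_length_bp": self.chromosome_length_bp,
            "n_founder_haplotypes": self.n_founder_haplotypes,
            "n_subpops": self.n_subpops,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive, got {value}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0, 1)")
        for trait, h2 in self.h2.items():
            if not 0.0 <= h2 < 1.0:
                raise ConfigurationError(f"h2[{trait}]={h2} outside [0, 1)")
        if self.variants_per_chromosome > self.chromosome_length_bp:
            raise ConfigurationError("more variants than base pairs per chromosome")
        chroms = set(self.chromosome_names())
        for q in self.qtl:
            if q.chrom not in chroms:
                raise ConfigurationError(f"QTL chromosome {q.chrom!r} not simulated")
            if not 1 <= q.pos <= self.chromosome_length_bp:
                raise ConfigurationError(f"QTL position {q.pos} outside chromosome")
            if q.trait not in SIM_TRAITS:
                raise ConfigurationError(
                    f"QTL trait {q.trait!r}; simulated traits are {SIM_TRAITS}"
                )
            if self.h2.get(q.trait, 0.0) == 0.0:
                raise ConfigurationError(
                    f"QTL on trait {q.trait!r} requires h2[{q.trait}] > 0"
                )
            if not 0.0 < q.maf <= 0.5:
                raise ConfigurationError("QTL maf must be in (0, 0.5]")

    def chromosome_names(self) -> list:
        names = [str(i + 1) for i in range(self.n_chromosomes)]
        if self.include_x:
            names.append("X")
        return names

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["qtl"] = [dataclasses.asdict(q) for q in self.qtl]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["qtl"] = tuple(QTLSpec(**q) for q in d.get("qtl", ()))
        for key in ("maf_range", "rare_maf_range", "lactation_scale",
                    "lactation_retention"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated data for recovery testing."""

    causal_variants: pd.DataFrame  # columns: variant_id, trait, effect
    cluster_label: pd.Series  # per-cow subpopulation id (1-based)
    variance_components: dict  # trait -> (sigma2_g, sigma2_e)
    genetic_values: pd.DataFrame  # per-cow total genetic value per trait


# ----------------------------------------------------------------------
# deterministic sub-streams so genotype and phenotype stages can be called
# independently yet share pedigree/covariate assignments
_STREAM_PEDIGREE, _STREAM_GENO, _STREAM_PHENO = 1, 2, 3


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _pedigree(config: SimConfig) -> pd.DataFrame:
    """Per-cow sire, dam, farm, birth-year/season, subpopulation (deterministic)."""
    rng = _rng(config, _STREAM_PEDIGREE)
    n = config.n_individuals
    sire = rng.integers(config.n_sires, size=n)
    if config.n_dams > 0:
        dam = rng.integers(config.n_dams, size=n)
    else:
        dam = np.arange(n)
    sire_subpop = np.arange(config.n_sires) % config.n_subpops
    subpop = sire_subpop[sire]
    farm = rng.integers(config.n_farms, size=n)
    birth_year = config.first_birth_year + rng.integers(config.birth_years, size=n)
    birth_season = rng.integers(1, 5, size=n)
    afc = np.round(rng.normal(760.0, 60.0, size=n)).astype(int)
    return pd.DataFrame(
        {
            "cow_id": [f"cow{i:05d}" for i in range(n)],
            "sire": [f"sire{s:03d}" for s in sire],
            "dam": [f"dam{d:05d}" for d in dam],
            "dam_idx": dam,
            "sire_idx": sire,
            "subpop": subpop + 1,
            "farm": [f"farm{f}" for f in farm],
            "birth_year": birth_year,
            "birth_season": birth_season,
            "age_first_calving": afc,
        }
    )


def _draw_maf(rng: np.random.Generator, m: int, config: SimConfig) -> np.ndarray:
    lo, hi = config.maf_range
    f = rng.uniform(lo, hi, size=m)
    if config.rare_tail_fraction > 0:
        rare = rng.random(m) < config.rare_tail_fraction
        rlo, rhi = config.rare_maf_range
        f[rare] = rng.uniform(rlo, rhi, size=int(rare.sum()))
    return f


def _block_index(rng, positions: np.ndarray, config: SimConfig) -> np.ndarray:
    """Assign each variant to an LD block with Exp-distributed block lengths."""
    m = len(positions)
    mean_bp = config.ld_block_mean_kb * 1000.0
    length = config.chromosome_length_bp
    if mean_bp <= 0 or length / max(mean_bp, 1e-9) > 5 * m:
        return np.arange(m)  # effectively independent variants
    n_blocks = int(np.ceil(length / mean_bp * 3)) + 8
    edges = np.cumsum(rng.exponential(mean_bp, size=n_blocks))
    while edges[-1] < length:  # pragma: no cover - extremely unlikely
        edges = np.concatenate([edges, edges[-1] + np.cumsum(
            rng.exponential(mean_bp, size=n_blocks))])
    return np.searchsorted(edges, positions, side="right")


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Simulate diploid dosages for the configured herd.

    Returns a :class:`GenotypeMatrix` with ALT-allele dosages and ``NaN``
    missing calls at the configured rate.
    """
    ped = _pedigree(config)
    rng = _rng(config, _STREAM_GENO)
    n = config.n_individuals
    K = config.n_founder_haplotypes
    subpop = ped["subpop"].to_numpy() - 1
    sire_idx = ped["sire_idx"].to_numpy()
    dam_idx = ped["dam_idx"].to_numpy()
    n_dams = int(dam_idx.max()) + 1

    meta_frames = []
    dosage_parts = []
    qtl_by_chrom: dict = {}
    for q in config.qtl:
        qtl_by_chrom.setdefault(q.chrom, []).append(q)

    for chrom in config.chromosome_names():
        m = config.variants_per_chromosome
        positions = np.sort(
            rng.choice(config.chromosome_length_bp, size=m, replace=False) + 1
        )
        # plant QTL variants at their exact positions (replace nearest site)
        for q in qtl_by_chrom.get(chrom, []):
            if q.pos not in positions:
                positions[np.argmin(np.abs(positions - q.pos))] = q.pos
        positions = np.unique(positions)
        m = len(positions)
        blk = _block_index(rng, positions, config)

        # ancestral ALT frequency: MAF spectrum with random minor orientation
        maf = _draw_maf(rng, m, config)
        flip = rng.random(m) < 0.5
        p_anc = np.where(flip, 1.0 - maf, maf)
        qtl_cols = {}
        for q in qtl_by_chrom.get(chrom, []):
            j = int(np.searchsorted(positions, q.pos))
            qtl_cols[j] = q
            p_anc[j] = q.maf

        n_blocks = int(blk.max()) + 1
        # carrier ranks: nested carrier sets along one founder ordering per
        # block give star-genealogy LD (D' ~ 1); "recombinant" variants get
        # their own ordering and decouple from their neighbours
        rank = np.argsort(rng.random((n_blocks, K)), axis=1)[blk]  # (m, K)
        fresh = rng.random(m) < config.ld_noise
        for j in qtl_cols:  # planted QTL always ride the block haplotypes
            fresh[j] = False
        if fresh.any():
            rank[fresh] = np.argsort(rng.random((int(fresh.sum()), K)), axis=1)

        # founder pools, optionally diverged across subpopulations
        founders = np.empty((config.n_subpops, K, m), dtype=np.uint8)
        for sp in range(config.n_subpops):
            if config.fst > 0 and config.n_subpops > 1:
                F = config.fst
                a = p_anc * (1 - F) / F
                b = (1 - p_anc) * (1 - F) / F
                p_sp = np.clip(rng.beta(a, b), 0.005, 0.995)
            else:
                p_sp = p_anc
            carriers = np.clip(np.rint(p_sp * K), 0, K).astype(np.int64)
            founders[sp] = (rank < carriers[:, None]).T.astype(np.uint8)
        # sire gametes: founder index per block for each of two haplotypes
        sire_h = rng.integers(K, size=(config.n_sires, 2, n_blocks))
        dam_h = rng.integers(K, size=(n_dams, 2, n_blocks))
        coin_p = rng.integers(2, size=(n, n_blocks))
        coin_m = rng.integers(2, size=(n, n_blocks))
        pat_idx = sire_h[sire_idx[:, None], coin_p, np.arange(n_blocks)[None, :]]
        mat_idx = dam_h[dam_idx[:, None], coin_m, np.arange(n_blocks)[None, :]]

        dosage = np.empty((n, m), dtype=np.float32)
        chunk = max(1, 4_000_000 // max(n, 1))
        for start in range(0, m, chunk):
            sl = slice(start, min(start + chunk, m))
            blk_sl = blk[sl]
            cols = np.arange(sl.start, sl.stop)
            for sp in range(config.n_subpops):
                rows = np.nonzero(subpop == sp)[0]
                if rows.size == 0:
                    continue
                fp = founders[sp]
                pat = fp[pat_idx[rows][:, blk_sl], cols[None, :]]
                mat = fp[mat_idx[rows][:, blk_sl], cols[None, :]]
                dosage[rows[:, None], cols[None, :]] = (pat + mat).astype(np.float32)

        if config.missing_rate > 0:
            miss = rng.random((n, m)) < config.missing_rate
            dosage[miss] = np.nan

        ref = np.full(m, "A")
        alt = np.full(m, "C")
        meta_frames.append(
            pd.DataFrame(
                {
                    "id": [f"var_{chrom}_{p}" for p in positions],
                    "chrom": chrom,
                    "pos": positions,
                    "ref": ref,
                    "alt": alt,
                }
            )
        )
        dosage_parts.append(dosage)

    variants = pd.concat(meta_frames, ignore_index=True)
    dosage = np.concatenate(dosage_parts, axis=1)
    return GenotypeMatrix(
        ids=ped["cow_id"].to_numpy(), variants=variants, dosage=dosage
    )


# ----------------------------------------------------------------------
def _level_effects(rng, labels: np.ndarray, magnitude: float, sd: float) -> np.ndarray:
    """Random per-level effects (N(0, (magnitude*sd)^2)) mapped onto rows."""
    levels, inverse = np.unique(labels, return_inverse=True)
    eff = rng.normal(0.0, magnitude * sd, size=len(levels))
    return eff[inverse]


def simulate_phenotypes(
    geno: GenotypeMatrix, config: SimConfig
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate 305-day lactation records for the cows in ``geno``.

    Returns a long-format record table (one row per cow x lactation actually
    recorded) and the :class:`SimTruth` needed for recovery tests. The
    record table carries milk/fat/protein yields in kg plus all model
    covariates; short lactations (< 270 days in milk) are emitted so the
    full-lactation filter has work to do.
    """
    ped = _pedigree(config)
    if not np.array_equal(ped["cow_id"].to_numpy(), geno.ids):
        raise ValueError("genotypes do not cover the configured cohort")
    rng = _rng(config, _STREAM_PHENO)
    n = config.n_individuals

    id_to_col = {v: j for j, v in enumerate(geno.variants["id"])}
    for q in config.qtl:
        if f"var_{q.chrom}_{q.pos}" not in id_to_col:
            raise ValueError(f"causal variant at {q.chrom}:{q.pos} absent from genotypes")

    # mean-imputed dosage accessor (phenotypes must not depend on missingness)
    def dose(col: int) -> np.ndarray:
        d = geno.dosage[:, col].astype(float)
        if np.isnan(d).any():
            d = np.where(np.isnan(d), np.nanmean(d), d)
        return d

    genetic = {}
    var_comp = {}
    causal_rows = []
    for trait in SIM_TRAITS:
        h2 = config.h2.get(trait, 0.0)
        sd = config.trait_sd[trait]
        sigma_p2 = sd * sd
        qtl_part = np.zeros(n)
        for q in config.qtl:
            if q.trait != trait:
                continue
            vid = f"var_{q.chrom}_{q.pos}"
            qtl_part += q.effect * dose(id_to_col[vid])
            causal_rows.append({"variant_id": vid, "trait": trait,
                                "effect": q.effect})
        if h2 == 0.0:
            genetic[trait] = np.zeros(n)
            var_comp[trait] = (0.0, sigma_p2)
            continue
        sigma_g2 = h2 * sigma_p2
        qtl_part -= qtl_part.mean()
        qtl_var = float(qtl_part @ qtl_part) / n
        if qtl_var >= sigma_g2:
            g = qtl_part
            sigma_g2 = qtl_var if qtl_var > 0 else sigma_g2
        else:
            n_poly = min(config.n_polygenic, geno.n_variants)
            cols = rng.choice(geno.n_variants, size=n_poly, replace=False)
            w = rng.normal(size=n_poly)
            poly = np.zeros(n)
            for j, wj in zip(cols, w):
                poly += wj * dose(int(j))
            poly -= poly.mean()
            if qtl_var > 0:  # orthogonalize so the variance split is exact
                poly -= (poly @ qtl_part) / (qtl_part @ qtl_part) * qtl_part
            poly_sd = np.sqrt(float(poly @ poly) / n)
            target = np.sqrt(sigma_g2 - qtl_var)
            poly = poly * (target / poly_sd) if poly_sd > 0 else poly
            g = qtl_part + poly
        sigma_g2 = float(g @ g) / n
        sigma_e2 = sigma_g2 * (1.0 - h2) / h2 if sigma_g2 > 0 else sigma_p2
        genetic[trait] = g
        var_comp[trait] = (sigma_g2, sigma_e2)

    # fixed covariate effects per trait (shared across lactations)
    cov_value = {t: np.zeros(n) for t in SIM_TRAITS}
    for trait in SIM_TRAITS:
        sd = config.trait_sd[trait]
        eff = config.covariate_effects
        cov = np.zeros(n)
        cov += _level_effects(rng, ped["farm"].to_numpy(), eff.get("farm", 0), sd)
        cov += _level_effects(rng, ped["sire"].to_numpy(), eff.get("sire", 0), sd)
        cov += _level_effects(rng, ped["birth_year"].to_numpy(),
                              eff.get("birth_year", 0), sd)
        cov += _level_effects(rng, ped["birth_season"].to_numpy(),
                              eff.get("birth_season", 0), sd)
        afc = ped["age_first_calving"].to_numpy()
        cov += eff.get("age_first_calving", 0) * sd * (afc - afc.mean())
        if config.confound_sd > 0 and config.n_subpops > 1:
            shift = rng.normal(0.0, config.confound_sd * sd, size=config.n_subpops)
            cov += shift[ped["subpop"].to_numpy() - 1]
        cov_value[trait] = cov

    records = []
    present = np.ones(n, dtype=bool)
    for li, lact in enumerate((1, 2, 3)):
        present = present & (rng.random(n) < config.lactation_retention[li])
        rows = np.nonzero(present)[0]
        if rows.size == 0:
            continue
        short = rng.random(n) < config.short_lactation_rate
        dim = rng.integers(270, 366, size=n)
        dim[short] = rng.integers(150, 270, size=int(short.sum()))
        cy = ped["birth_year"].to_numpy() + 2 + li
        cs = rng.integers(1, 5, size=n)
        cy_eff = {}
        cs_eff = {}
        values = {}
        for trait in SIM_TRAITS:
            sd = config.trait_sd[trait]
            eff = config.covariate_effects
            cy_eff[trait] = _level_effects(rng, cy, eff.get("calving_year", 0), sd)
            cs_eff[trait] = _level_effects(rng, cs, eff.get("calving_season", 0), sd)
            sigma_e2 = var_comp[trait][1]
            e = rng.normal(size=n)
            e = (e - e.mean()) / e.std() * np.sqrt(sigma_e2)
            mean = config.trait_mean[trait]
            if trait == "milk_kg":
                mean = mean * config.lactation_scale[li]
            values[trait] = (
                mean + cov_value[trait] + cy_eff[trait] + cs_eff[trait]
                + genetic[trait] + e
            )
        milk = np.maximum(values["milk_kg"], 500.0)
        fat_pct = np.clip(values["fat_pct"], 1.0, 9.0)
        protein_pct = np.clip(values["protein_pct"], 1.0, 9.0)
        fat = milk * fat_pct / 100.0
        protein = milk * protein_pct / 100.0
        for i in rows:
            records.append(
                (
                    ped.at[i, "cow_id"], lact, int(dim[i]),
                    round(float(milk[i]), 1), round(float(fat[i]), 2),
                    round(float(protein[i]), 2),
                    ped.at[i, "farm"], ped.at[i, "sire"],
                    int(ped.at[i, "birth_year"]), int(ped.at[i, "birth_season"]),
                    int(cy[i]), int(cs[i]), int(ped.at[i, "age_first_calving"]),
                )
            )

    record_df = pd.DataFrame(
        records,
        columns=[
            "cow_id", "lactation", "dim", "milk_kg", "fat_kg", "protein_kg",
            "farm", "sire", "birth_year", "birth_season", "calving_year",
            "calving_season", "age_first_calving",
        ],
    )
    truth = SimTruth(
        causal_variants=pd.DataFrame(
            causal_rows, columns=["variant_id", "trait", "effect"]
        ),
        cluster_label=pd.Series(
            ped["subpop"].to_numpy(), index=ped["cow_id"], name="cluster"
        ),
        variance_components=var_comp,
        genetic_values=pd.DataFrame(genetic, index=ped["cow_id"]),
    )
    return record_df, truth


def covariate_table(config: SimConfig) -> pd.DataFrame:
    """Cow-level covariates (farm, sire, birth year/season, AFC, subpop)."""
    ped = _pedigree(config)
    return ped.drop(columns=["dam_idx", "sire_idx"]).set_index("cow_id")
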
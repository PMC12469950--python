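"""Synthetic populations, pedigrees, SNP genotypes and mtDNA repeat profiles.

The generator emulates the data structure of a nest-based conservation
genomics study of an endangered freshwater turtle: several river
populations diverged to a target Fst, nesting females laying one or more
clutches per season, multiple paternity within clutches, sperm storage
(re-use of a stored father in a later clutch), RADseq-style SNP panels with
per-genotype missingness and read depths, and maternally transmitted
heteroplasmic mtDNA repeat-copy pools passed through a germline bottleneck.

Model choices
-------------
* Allele-frequency divergence follows the Balding-Nichols Beta model
  ``Beta(p(1-F)/F, (1-p)(1-F)/F)``, independent across loci, which has mean
  ``p`` and among-population variance ``F p (1-p)`` so the Weir-Cockerham
  estimator recovers ``target_fst`` on large panels.
* Founders are in Hardy-Weinberg proportions; offspring receive one
  uniformly chosen allele per parent per locus (Mendelian transmission, no
  linkage).
* Missingness is MCAR, independent per genotype call.
* mtDNA transmission samples ``bottleneck_n`` molecules multinomially from
  the mother's pool; each transmitted unit slips +-1 repeat copy with
  probability ``slippage_rate`` per transmission (one generation).
* A single root seed feeds per-stage child streams, so e.g. changing the
  number of loci never perturbs the pedigree draws.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix
from .mtdna import RepeatProfile, read_profiles_tsv, write_profiles_tsv
from .vcfio import read_vcf, write_vcf

_STAGES = ("freqs", "pedigree", "genotypes", "mtdna", "missing", "depth")


class ConfigurationError(ValueError):
    pass


@dataclass
class MtdnaConfig:
    """Heteroplasmic repeat-pool model for founding mothers and transmission.

    ``copy_range`` matches the observed span of the 8-bp repeat (13-26
    copies).  The germline bottleneck size is not known for this species;
    ``bottleneck_n=20`` is a free-parameter choice that reproduces visible
    sibling-to-sibling variation in band fractions without losing the
    mother's dominant band.
    """

    copy_range: tuple[int, int] = (13, 26)
    bottleneck_n: int = 20
    slippage_rate: float = 0.01
    detection_threshold: float = 0.05
    founder_band_probs: tuple[float, ...] = (0.35, 0.40, 0.25)  # P(1, 2, 3 bands)
    dominant_fraction_range: tuple[float, float] = (0.6, 0.9)


@dataclass
class SimulationConfig:
    """Study-scale defaults: 20 nesting females, 15 breeding males, 30 nests
    of 4 sampled hatchlings, 3000 SNPs in one population."""

    n_populations: int = 1
    target_fst: float = 0.15
    n_loci: int = 3000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_mothers: int = 20
    n_fathers: int = 15
    n_nests: int | None = 30  # exact total; falls back to nests_per_mother
    nests_per_mother: float = 1.5  # mean when n_nests is None
    clutch_size: int = 4
    p_multiple_paternity: float = 0.3
    p_sperm_storage: float = 0.2
    season_span_days: int = 90
    season_year: int = 2021
    missing_rate: float = 0.05
    depth_mean: float | None = 65.0
    depth_sd: float = 16.0
    mtdna: MtdnaConfig = field(default_factory=MtdnaConfig)
    rng_seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.target_fst < 1.0):
            raise ConfigurationError("target_fst must be in [0, 1)")
        for name in ("p_multiple_paternity", "p_sperm_storage", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1]")
        for name in (
            "n_populations",
            "n_loci",
            "n_mothers",
            "clutch_size",
            "season_span_days",
        ):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_fathers < 1 and self.clutch_size > 0:
            raise ConfigurationError("offspring requested but n_fathers = 0")
        if not (0.0 <= self.mtdna.slippage_rate <= 1.0):
            raise ConfigurationError("slippage_rate must be in [0, 1]")
        if self.mtdna.bottleneck_n < 1:
            raise ConfigurationError("bottleneck_n must be >= 1")
        if self.mtdna.copy_range[0] < 1 or self.mtdna.copy_range[0] > self.mtdna.copy_range[1]:
            raise ConfigurationError("invalid mtDNA copy_range")

    def stream(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage RNG derived from the root seed."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.rng_seed), _STAGES.index(stage)])
        )


@dataclass
class PopulationFrequencies:
    ancestral_freq: np.ndarray  # per locus
    subpop_freq: np.ndarray  # loci x populations

    @property
    def n_populations(self) -> int:
        return self.subpop_freq.shape[1]


def simulate_allele_frequencies(config: SimulationConfig) -> PopulationFrequencies:
    """Ancestral MAFs ~ U(maf_range); Balding-Nichols divergence to target Fst.

    ``target_fst = 0`` is the degenerate (point-mass) limit of the Beta and
    yields subpopulation frequencies identical to the ancestral ones.
    """
    config.validate()
    rng = config.stream("freqs")
    lo, hi = config.maf_range
    p0 = rng.uniform(lo, hi, size=config.n_loci)
    F = config.target_fst
    if F == 0.0:
        sub = np.tile(p0[:, None], (1, config.n_populations))
    else:
        a = p0 * (1 - F) / F
        b = (1 - p0) * (1 - F) / F
        sub = rng.beta(a[:, None], b[:, None], size=(config.n_loci, config.n_populations))
    return PopulationFrequencies(p0, sub)


@dataclass
class EventRegistry:
    """Ground-truth reproductive events, derived from the realized pedigree."""

    multiple_paternity_nests: list[str]
    sperm_storage_events: list[dict]
    repeat_clutch_events: list[dict]


@dataclass
class PedigreeTruth:
    offspring: pd.DataFrame  # offspring_id, mother_id, father_id, nest_id, population_id, lay_date
    mother_pools: dict[str, dict[int, float]]
    registry: EventRegistry
    mothers: list[str]
    fathers: list[str]
    mother_population: dict[str, int]
    father_population: dict[str, int]

    def n_mothers_participating(self) -> int:
        return self.offspring["mother_id"].nunique()

    def n_fathers_participating(self) -> int:
        return self.offspring["father_id"].nunique()

    def maternal_partition(self) -> dict[str, str]:
        return dict(zip(self.offspring["offspring_id"], self.offspring["mother_id"]))

    def metadata(self) -> pd.DataFrame:
        md = self.offspring[["offspring_id", "nest_id", "population_id", "lay_date"]].copy()
        md.columns = ["sample_id", "nest_id", "site", "lay_date"]
        md["site"] = "site" + (md["site"] + 1).astype(str)
        return md


def _founder_pool(rng: np.random.Generator, cfg: MtdnaConfig) -> dict[int, float]:
    lo, hi = cfg.copy_range
    n_bands = int(rng.choice(np.arange(1, len(cfg.founder_band_probs) + 1), p=cfg.founder_band_probs))
    dominant = int(rng.integers(lo, hi + 1))
    bands = [dominant]
    offsets = [d for d in (-2, -1, 1, 2) if lo <= dominant + d <= hi]
    rng.shuffle(offsets)
    for d in offsets[: n_bands - 1]:
        bands.append(dominant + d)
    dfrac = rng.uniform(*cfg.dominant_fraction_range)
    if len(bands) == 1:
        return {dominant: 1.0}
    minor = rng.dirichlet(np.ones(len(bands) - 1)) * (1 - dfrac)
    pool = {dominant: dfrac}
    for b, f in zip(bands[1:], minor):
        pool[b] = float(f)
    return dict(sorted(pool.items()))


def simulate_pedigree(config: SimulationConfig) -> PedigreeTruth:
    """Mothers, nests with lay dates, father assignments and mtDNA pools.

    Father choice per nest excludes the mother's previously used fathers
    unless a sperm-storage event (probability ``p_sperm_storage`` for
    clutches after the first) re-uses one, so with ``p_sperm_storage = 0``
    no father ever spans two nests of one mother.  With probability
    ``p_multiple_paternity`` a nest receives a second father and each father
    sires at least one offspring in it.  The event registry is derived from
    the realized pedigree, so its counts are exact by construction.
    """
    config.validate()
    rng = config.stream("pedigree")
    mothers = [f"M{i+1:02d}" for i in range(config.n_mothers)]
    fathers = [f"F{i+1:02d}" for i in range(config.n_fathers)]
    mother_pop = {m: i % config.n_populations for i, m in enumerate(mothers)}
    father_pop = {f: i % config.n_populations for i, f in enumerate(fathers)}

    # nest counts per mother
    if config.n_nests is not None:
        if config.n_nests < 1:
            raise ConfigurationError("n_nests must be positive")
        counts = np.zeros(config.n_mothers, dtype=int)
        counts[: min(config.n_mothers, config.n_nests)] = 1
        extra = config.n_nests - counts.sum()
        if extra > 0:
            counts += np.bincount(
                rng.integers(0, config.n_mothers, size=extra),
                minlength=config.n_mothers,
            )
    else:
        counts = 1 + rng.poisson(max(config.nests_per_mother - 1.0, 0.0), config.n_mothers)

    season_start = datetime.date(config.season_year, 5, 1)
    rows = []
    nest_no = 0
    oid = 0
    for m, n_nests_m in zip(mothers, counts):
        if n_nests_m == 0:
            continue
        offsets = sorted(rng.choice(config.season_span_days, size=n_nests_m, replace=False))
        used: list[str] = []
        for date_offset in offsets:
            nest_no += 1
            nest_id = f"N{nest_no:02d}"
            lay_date = season_start + datetime.timedelta(days=int(date_offset))
            nest_fathers = [
                _draw_father(rng, fathers, used, config.p_sperm_storage, mother_pop[m], father_pop)
            ]
            clutch = config.clutch_size
            if (
                clutch >= 2
                and config.n_fathers >= 2
                and rng.random() < config.p_multiple_paternity
            ):
                second = _draw_father(
                    rng,
                    fathers,
                    used + nest_fathers,
                    0.0,
                    mother_pop[m],
                    father_pop,
                )
                nest_fathers.append(second)
            for f in nest_fathers:
                if f not in used:
                    used.append(f)
            # assign offspring to fathers; in MP nests each father sires >= 1
            assignment = [nest_fathers[0]] * clutch
            if len(nest_fathers) == 2:
                n_second = int(rng.integers(1, clutch))
                pick = rng.choice(clutch, size=n_second, replace=False)
                for i in pick:
                    assignment[i] = nest_fathers[1]
            for f in assignment:
                oid += 1
                rows.append(
                    {
                        "offspring_id": f"T{oid:03d}",
                        "mother_id": m,
                        "father_id": f,
                        "nest_id": nest_id,
                        "population_id": mother_pop[m],
                        "lay_date": lay_date.isoformat(),
                    }
                )

    offspring = pd.DataFrame(rows)
    pools = {m: _founder_pool(rng, config.mtdna) for m in mothers}
    registry = _build_registry(offspring)
    return PedigreeTruth(offspring, pools, registry, mothers, fathers, mother_pop, father_pop)


def _draw_father(
    rng: np.random.Generator,
    fathers: list[str],
    used: list[str],
    p_storage: float,
    pop: int,
    father_pop: dict[str, int],
) -> str:
    """One father for a clutch; storage re-uses, otherwise avoid re-use."""
    same_pop = [f for f in fathers if father_pop[f] == pop] or list(fathers)
    used_here = [f for f in used if f in same_pop]
    if used_here and rng.random() < p_storage:
        return str(rng.choice(used_here))
    fresh = [f for f in same_pop if f not in used]
    if not fresh:
        raise ConfigurationError(
            "not enough fathers to avoid re-use; increase n_fathers or allow sperm storage"
        )
    return str(rng.choice(fresh))


def _build_registry(offspring: pd.DataFrame) -> EventRegistry:
    mp_nests = []
    for nest, grp in offspring.groupby("nest_id", sort=True):
        if grp["father_id"].nunique() >= 2:
            mp_nests.append(str(nest))
    storage = []
    repeat = []
    for mother, grp in offspring.groupby("mother_id", sort=True):
        nest_info = (
            grp.groupby("nest_id")
            .agg(lay_date=("lay_date", "first"))
            .reset_index()
            .sort_values("lay_date")
        )
        nests = list(nest_info["nest_id"])
        dates = {r.nest_id: r.lay_date for r in nest_info.itertuples()}
        if len(nests) >= 2:
            years = {d[:4] for d in dates.values()}
            for year in sorted(years):
                same_year = [n for n in nests if dates[n][:4] == year]
                if len(same_year) >= 2:
                    repeat.append(
                        {
                            "mother": mother,
                            "year": int(year),
                            "nests": same_year,
                            "dates": [dates[n] for n in same_year],
                        }
                    )
        by_father = grp.groupby("father_id")["nest_id"].agg(lambda s: sorted(set(s)))
        for father, fnests in by_father.items():
            if len(fnests) >= 2:
                for a, b in zip(fnests, fnests[1:]):
                    da = datetime.date.fromisoformat(dates[a])
                    db = datetime.date.fromisoformat(dates[b])
                    if da != db:
                        storage.append(
                            {
                                "mother": mother,
                                "father": father,
                                "nests": sorted([a, b]),
                                "gap_days": abs((db - da).days),
                            }
                        )
    return EventRegistry(mp_nests, storage, repeat)


# ---------------------------------------------------------------------------
# Genotypes


def simulate_genotypes(
    pedigree: PedigreeTruth,
    freqs: PopulationFrequencies,
    config: SimulationConfig,
    include_founders: bool = False,
) -> GenotypeMatrix:
    """Founders binomial from their population frequencies, offspring by
    Mendelian transmission; MCAR missingness applied to the returned panel."""
    for pop in set(pedigree.mother_population.values()) | set(
        pedigree.father_population.values()
    ):
        if pop >= freqs.n_populations:
            raise ConfigurationError(f"population {pop} missing from frequencies")
    rng = config.stream("genotypes")
    L = freqs.subpop_freq.shape[0]
    founder_geno: dict[str, np.ndarray] = {}
    for parent in pedigree.mothers + pedigree.fathers:
        pop = pedigree.mother_population.get(parent, pedigree.father_population.get(parent))
        founder_geno[parent] = rng.binomial(2, freqs.subpop_freq[:, pop]).astype(float)

    ids, rowsx = [], []
    for rec in pedigree.offspring.itertuples():
        m = founder_geno[rec.mother_id]
        f = founder_geno[rec.father_id]
        child = (rng.random(L) < m / 2.0).astype(float) + (rng.random(L) < f / 2.0)
        ids.append(rec.offspring_id)
        rowsx.append(child)
    if include_founders:
        for parent in pedigree.mothers + pedigree.fathers:
            ids.append(parent)
            rowsx.append(founder_geno[parent])
    dosage = np.array(rowsx) if rowsx else np.empty((0, L))

    if config.missing_rate > 0 and dosage.size:
        miss_rng = config.stream("missing")
        mask = miss_rng.random(dosage.shape) < config.missing_rate
        dosage = np.where(mask, np.nan, dosage)

    locus_ids = [f"L{j+1:05d}" for j in range(L)]
    return GenotypeMatrix(ids, locus_ids, dosage)


def simulate_unrelated_panel(
    freqs: PopulationFrequencies,
    n_per_pop: int,
    config: SimulationConfig,
    prefix: str = "U",
    seed_offset: int = 1,
) -> tuple[GenotypeMatrix, dict[str, str]]:
    """Unrelated HWE individuals drawn directly from population frequencies.

    Returns the panel and a sample -> population-label map; useful for the
    population-structure estimators, which assume unrelated samples.
    ``seed_offset`` decouples this stream from :func:`simulate_genotypes`
    so the two can coexist in one run.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [int(config.rng_seed), _STAGES.index("genotypes"), int(seed_offset)]
        )
    )
    ids, rows, pops = [], [], {}
    for pop in range(freqs.n_populations):
        p = freqs.subpop_freq[:, pop]
        for i in range(n_per_pop):
            sid = f"{prefix}{pop+1}_{i+1:03d}"
            ids.append(sid)
            rows.append(rng.binomial(2, p).astype(float))
            pops[sid] = f"pop{pop+1}"
    dosage = np.array(rows)
    if config.missing_rate > 0:
        mask = config.stream("missing").random(dosage.shape) < config.missing_rate
        dosage = np.where(mask, np.nan, dosage)
    locus_ids = [f"L{j+1:05d}" for j in range(freqs.subpop_freq.shape[0])]
    return GenotypeMatrix(ids, locus_ids, dosage), pops


def simulate_depth(config: SimulationConfig, shape: tuple[int, int]) -> np.ndarray | None:
    """Per-genotype read depths, negative-binomial around the panel mean."""
    if config.depth_mean is None:
        return None
    rng = config.stream("depth")
    m, sd = config.depth_mean, config.depth_sd
    var = max(sd**2, m + 1e-9)
    if var <= m:
        return np.full(shape, int(round(m)))
    r = m**2 / (var - m)
    p = r / (r + m)
    return np.maximum(rng.negative_binomial(r, p, size=shape), 1)


@dataclass
class KinshipCalibrationPanel:
    """Known-relationship pairs plus anchor groups, for calibrating the
    normalized-IBS statistic against its analytic expectations."""

    genotypes: GenotypeMatrix
    full_sib_pairs: list[tuple[str, str]]
    half_sib_pairs: list[tuple[str, str]]
    unrelated_pairs: list[tuple[str, str]]
    anchor_groups: dict[str, str]  # sample -> "A" / "B"


def simulate_kinship_calibration(
    n_pairs: int = 64,
    n_loci: int = 2000,
    maf_range: tuple[float, float] = (0.05, 0.5),
    n_anchor: int = 15,
    rng_seed: int = 0,
    related_fathers: bool = False,
) -> KinshipCalibrationPanel:
    """Full-sib and half-sib pairs from unrelated HWE founders, plus two
    groups of unrelated individuals from the same population to anchor the
    normalization.

    ``related_fathers=True`` makes each half-sib pair's two fathers full
    sibs of each other, which adds paternal-side identity by descent and
    shifts the half-sib expectation upward — the signature of breeding
    among relatives.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 97]))
    lo, hi = maf_range
    p = rng.uniform(lo, hi, n_loci)

    def founder() -> np.ndarray:
        return rng.binomial(2, p).astype(float)

    def child(m: np.ndarray, f: np.ndarray) -> np.ndarray:
        maternal = (rng.random(n_loci) < m / 2.0).astype(float)
        paternal = (rng.random(n_loci) < f / 2.0).astype(float)
        return maternal + paternal

    ids: list[str] = []
    rows: list[np.ndarray] = []
    fs_pairs, hs_pairs, un_pairs = [], [], []
    groups: dict[str, str] = {}

    for i in range(n_pairs):
        mother, father = founder(), founder()
        a, b = f"FS{i:03d}a", f"FS{i:03d}b"
        ids += [a, b]
        rows += [child(mother, father), child(mother, father)]
        fs_pairs.append((a, b))

    for i in range(n_pairs):
        mother = founder()
        if related_fathers:
            gm, gf = founder(), founder()
            f1, f2 = child(gm, gf), child(gm, gf)
        else:
            f1, f2 = founder(), founder()
        a, b = f"HS{i:03d}a", f"HS{i:03d}b"
        ids += [a, b]
        rows += [child(mother, f1), child(mother, f2)]
        hs_pairs.append((a, b))

    for grp in ("A", "B"):
        for j in range(n_anchor):
            sid = f"{grp}{j:03d}"
            ids.append(sid)
            rows.append(founder())
            groups[sid] = grp
    a_ids = [s for s, g in groups.items() if g == "A"]
    b_ids = [s for s, g in groups.items() if g == "B"]
    un_pairs = list(zip(a_ids, b_ids))

    g = GenotypeMatrix(ids, [f"L{j+1:05d}" for j in range(n_loci)], np.array(rows))
    return KinshipCalibrationPanel(g, fs_pairs, hs_pairs, un_pairs, groups)


# ---------------------------------------------------------------------------
# mtDNA transmission


def simulate_mtdna_transmission(
    mother_pool: dict[int, float],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[int, float]:
    """One bottlenecked, slippage-mutated transmission of a repeat pool.

    Samples ``bottleneck_n`` mtDNA units multinomially from the mother's
    pool; each unit independently shifts its copy number by +-1 with
    probability ``slippage_rate``; returns surviving copy-number fractions.
    """
    if not mother_pool:
        raise ValueError("empty mtDNA pool")
    total = sum(mother_pool.values())
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"pool fractions sum to {total}, expected 1")
    if config.mtdna.bottleneck_n < 1:
        raise ValueError("bottleneck size must be >= 1")
    rng = rng if rng is not None else config.stream("mtdna")
    copies = sorted(mother_pool)
    probs = np.array([mother_pool[c] for c in copies]) / total
    counts = rng.multinomial(config.mtdna.bottleneck_n, probs)
    out: dict[int, int] = {}
    mu = config.mtdna.slippage_rate
    for c, k in zip(copies, counts):
        if k == 0:
            continue
        n_slip = rng.binomial(k, mu) if mu > 0 else 0
        n_up = rng.binomial(n_slip, 0.5) if n_slip else 0
        n_down = n_slip - n_up
        stay = k - n_slip
        for copy_n, cnt in ((c, stay), (c + 1, n_up), (max(c - 1, 1), n_down)):
            if cnt:
                out[copy_n] = out.get(copy_n, 0) + int(cnt)
    N = config.mtdna.bottleneck_n
    return {c: k / N for c, k in sorted(out.items())}


def simulate_offspring_profiles(
    pedigree: PedigreeTruth, config: SimulationConfig
) -> list[RepeatProfile]:
    rng = config.stream("mtdna")
    out = []
    for rec in pedigree.offspring.itertuples():
        bands = simulate_mtdna_transmission(
            pedigree.mother_pools[rec.mother_id], config, rng
        )
        out.append(RepeatProfile(rec.offspring_id, bands))
    return out


# ---------------------------------------------------------------------------
# Dataset bundle


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    depth: np.ndarray | None
    metadata: pd.DataFrame
    profiles: list[RepeatProfile]
    truth: dict


def simulate_dataset(config: SimulationConfig) -> tuple[
    GenotypeMatrix, np.ndarray | None, pd.DataFrame, list[RepeatProfile], PedigreeTruth
]:
    """End-to-end convenience: pedigree + genotypes + depths + profiles."""
    freqs = simulate_allele_frequencies(config)
    pedigree = simulate_pedigree(config)
    genotypes = simulate_genotypes(pedigree, freqs, config)
    depth = simulate_depth(config, genotypes.dosage.shape)
    profiles = simulate_offspring_profiles(pedigree, config)
    return genotypes, depth, pedigree.metadata(), profiles, pedigree


def write_dataset(
    genotypes: GenotypeMatrix,
    pedigree: PedigreeTruth,
    profiles: list[RepeatProfile],
    outdir,
    depth: np.ndarray | None = None,
) -> dict[str, Path]:
    """Write VCF + metadata TSV + profile TSV + ground-truth JSON.

    Sample IDs must agree across the three sample-keyed inputs; the first
    offending sample is named in the error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geno_ids = set(genotypes.sample_ids)
    meta = pedigree.metadata()
    meta_ids = set(meta["sample_id"])
    prof_ids = {p.sample_id for p in profiles}
    for sid in sorted(geno_ids ^ meta_ids):
        raise ValueError(f"sample {sid} not present in both genotypes and metadata")
    for sid in sorted(geno_ids ^ prof_ids):
        raise ValueError(f"sample {sid} not present in both genotypes and profiles")

    paths = {
        "vcf": outdir / "genotypes.vcf",
        "metadata": outdir / "metadata.tsv",
        "profiles": outdir / "profiles.tsv",
        "truth": outdir / "truth.json",
    }
    write_vcf(genotypes, paths["vcf"], depth=depth)
    meta.to_csv(paths["metadata"], sep="\t", index=False)
    write_profiles_tsv(profiles, paths["profiles"])
    truth = {
        "offspring": pedigree.offspring.to_dict(orient="records"),
        "mother_pools": {
            m: {str(c): f for c, f in pool.items()}
            for m, pool in pedigree.mother_pools.items()
        },
        "registry": asdict(pedigree.registry),
        "mothers": pedigree.mothers,
        "fathers": pedigree.fathers,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths


def read_dataset(outdir) -> SimulatedDataset:
    outdir = Path(outdir)
    genotypes, depth = read_vcf(outdir / "genotypes.vcf")
    metadata = pd.read_csv(outdir / "metadata.tsv", sep="\t")
    profiles = read_profiles_tsv(outdir / "profiles.tsv")
    with open(outdir / "truth.json") as fh:
        truth = json.load(fh)
    return SimulatedDataset(genotypes, depth, metadata, profiles, truth)
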
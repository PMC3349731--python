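"""Synthetic small-RNA cohort generator with full ground truth.

Emulates the study design end to end: a single synthetic chromosome carrying
miRNA hairpins (mature and star arms), snoRNAs, other ncRNAs and ncRNA
pseudogenes; 12-plex pooled libraries with a six-base index tag and a 3'
sequencing adapter on 37-base reads; log-normal small-RNA abundances;
sequence variants carried by Hardy-Weinberg genotypes; A-to-I editing at
fixed per-read rates; additive cis-eQTL effects on log2 expression;
batch/tag covariate effects; and metabolic phenotypes linearly coupled to
chosen small RNAs.  Every emitted read carries provenance in a truth
sidecar, closing the testing loop for each pipeline stage.

Scale defaults (read depth, genome length, gene counts) are desk-scale;
the cohort design itself (131 samples, 12 tags per pool, read length 37)
follows the study.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demux import ReadRecord
from .references import VariantSite

READ_LENGTH = 37
CLUSTER_BLOCK = 10_000     # miRNAs within this many bases share a cluster

#: Illumina v1.5-style small RNA 3' adapter and RNA linker
DEFAULT_ADAPTER3 = "ATCTCGTATGCCGTCTTCTGCTTG"
DEFAULT_LINKER = "CTGTAGGCACCATCAAT"


def default_tag_set(n: int = 12, min_dist: int = 3) -> tuple[str, ...]:
    """Deterministic set of six-base index tags with pairwise Hamming
    distance >= ``min_dist``, taken greedily in lexicographic order."""
    kept: list[str] = []
    for tag in itertools.product("ACGT", repeat=6):
        t = "".join(tag)
        if all(sum(a != b for a, b in zip(t, k)) >= min_dist for k in kept):
            kept.append(t)
            if len(kept) == n:
                break
    return tuple(kept)


DEFAULT_TAGS = default_tag_set()


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Effect lists use RNA ids as produced by the catalogue ("mir-7-5p",
    "mir-7-3p", "sno-3", ...).  Rates and frequencies must lie in [0, 1];
    a fixed seed makes every generated artefact byte-identical.
    """

    n_samples: int = 131
    n_mirna: int = 50
    n_snorna: int = 20
    n_other: int = 10
    n_pseudogene: int = 5
    n_unannotated: int = 5
    read_depth_mean: float = 20_000.0
    genome_length: int = 1_000_000
    tag_set: tuple[str, ...] = DEFAULT_TAGS
    adapter3: str = DEFAULT_ADAPTER3
    linker: str = DEFAULT_LINKER
    seed: int = 0
    # planted structure
    eqtl_effects: list = field(default_factory=list)   # (rna, snp, beta)
    edit_sites: list = field(default_factory=list)     # (rna, offset, rate)
    variant_sites: list = field(default_factory=list)  # (rna, offset, ref, alt, af)
    pheno_links: list = field(default_factory=list)    # (rna, trait, beta)
    n_null_snps: int = 20
    # nuisance structure
    error_rate: float = 0.005
    contaminant_fraction: float = 0.05
    star_fraction: float = 0.4
    cluster_fraction: float = 0.3
    baseline_log2: dict = field(default_factory=lambda: {
        "mature": 6.0, "star": 2.0, "snorna": 4.0, "other": 3.0})
    baseline_sd: float = 2.0
    noise_sd: float = 0.5
    batch_sd: float = 0.5
    pheno_noise: dict = field(default_factory=lambda: {
        "bmi": 3.5, "ptfm": 6.0, "insulin": 8.0, "glucose": 0.5})
    pheno_base: dict = field(default_factory=lambda: {
        "bmi": 27.0, "ptfm": 35.0, "insulin": 25.0, "glucose": 5.0})

    def __post_init__(self) -> None:
        if len(set(self.tag_set)) != len(self.tag_set):
            raise ValueError("index tags must be pairwise distinct")
        for _, _, rate in self.edit_sites:
            if not 0 <= rate <= 1:
                raise ValueError("edit rates must be in [0, 1]")
        for _, _, _, _, af in self.variant_sites:
            if not 0 <= af <= 1:
                raise ValueError("allele frequencies must be in [0, 1]")
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error rate must be in [0, 1]")
        if not 0 <= self.contaminant_fraction <= 1:
            raise ValueError("contaminant fraction must be in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class Catalogue:
    """Synthetic reference catalogue on a single chromosome."""

    genome: dict[str, str]
    hairpins: dict[str, str]
    arms: dict[str, tuple[str, int, int]]      # arm id -> (hairpin, start, end)
    ncrna: dict[str, str]
    pseudogenes: dict[str, str]
    placements: dict[str, list[tuple[str, int, int, str]]]
    clusters: dict[str, list[str]]             # cluster id -> hairpin ids
    conservation: pd.Series                    # per RNA product
    dnase_track: list[tuple[str, int, int]]
    unannotated: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def arm_sequence(self, arm_id: str) -> str:
        hp, start, end = self.arms[arm_id]
        return self.hairpins[hp][start:end]

    def rna_ids(self) -> list[str]:
        return list(self.arms) + list(self.ncrna) + list(self.unannotated)

    def annotations(self) -> pd.DataFrame:
        """Genomic intervals of quantified RNA products (first placement)."""
        rows = {}
        for arm_id, (hp, start, end) in self.arms.items():
            chrom, hstart, _, strand = self.placements[hp][0]
            rows[arm_id] = (chrom, hstart + start, hstart + end)
        for rid in self.ncrna:
            chrom, start, end, strand = self.placements[rid][0]
            rows[rid] = (chrom, start, end)
        return pd.DataFrame.from_dict(rows, orient="index",
                                      columns=["chrom", "start", "end"])


def make_reference_catalogue(cfg: SimConfig) -> Catalogue:
    """Lay out hairpins, snoRNAs, other ncRNA and pseudogenes on a random
    genome backbone; feature sequences are genome substrings so every RNA
    also maps to its genomic locus.

    miRNA hairpins placed within 10 kb of their predecessor share a cluster.
    """
    rng = cfg.rng(1)
    chrom = "chrS"
    genome_arr = rng.choice(list("ACGT"), size=cfg.genome_length)
    genome = "".join(genome_arr)

    hairpins: dict[str, str] = {}
    arms: dict[str, tuple[str, int, int]] = {}
    ncrna: dict[str, str] = {}
    pseudogenes: dict[str, str] = {}
    placements: dict[str, list] = {}
    clusters: dict[str, list[str]] = {}

    cursor = 1000
    cluster_id = 0
    prev_hp_pos = -10 ** 9
    for i in range(cfg.n_mirna):
        hp_len = int(rng.integers(70, 90))
        if i > 0 and rng.random() < cfg.cluster_fraction:
            gap = int(rng.integers(300, 3000))           # same 10 kb block
        else:
            gap = int(rng.integers(CLUSTER_BLOCK + 2000, CLUSTER_BLOCK + 12_000))
        cursor += gap
        if cursor + hp_len > cfg.genome_length - 1000:
            raise ValueError("requested feature counts exceed genome capacity")
        hp_id = f"hp-{i + 1}"
        seq = genome[cursor:cursor + hp_len]
        hairpins[hp_id] = seq
        placements[hp_id] = [(chrom, cursor, cursor + hp_len, "+")]
        if cursor - prev_hp_pos <= CLUSTER_BLOCK and i > 0:
            clusters[f"cluster-{cluster_id}"].append(hp_id)
        else:
            cluster_id += 1
            clusters[f"cluster-{cluster_id}"] = [hp_id]
        prev_hp_pos = cursor
        # 5' mature arm; star arm on the 3' side for a subset
        m_len = int(rng.integers(21, 24))
        m_start = int(rng.integers(8, 13))
        arms[f"mir-{i + 1}-5p"] = (hp_id, m_start, m_start + m_len)
        if rng.random() < cfg.star_fraction:
            s_len = int(rng.integers(21, 24))
            s_end = hp_len - int(rng.integers(2, 6))
            arms[f"mir-{i + 1}-3p"] = (hp_id, s_end - s_len, s_end)
        cursor += hp_len

    for i in range(cfg.n_snorna):
        length = int(rng.integers(60, 150))
        cursor += int(rng.integers(2000, 8000))
        if cursor + length > cfg.genome_length - 1000:
            raise ValueError("requested feature counts exceed genome capacity")
        rid = f"sno-{i + 1}"
        ncrna[rid] = genome[cursor:cursor + length]
        placements[rid] = [(chrom, cursor, cursor + length, "+")]
        cursor += length
    for i in range(cfg.n_other):
        length = int(rng.integers(50, 200))
        cursor += int(rng.integers(2000, 8000))
        if cursor + length > cfg.genome_length - 1000:
            raise ValueError("requested feature counts exceed genome capacity")
        rid = f"nc-{i + 1}"
        ncrna[rid] = genome[cursor:cursor + length]
        placements[rid] = [(chrom, cursor, cursor + length, "+")]
        cursor += length

    # pseudogenes: mutated hairpin copies written into the genome elsewhere
    genome_list = list(genome)
    for i in range(cfg.n_pseudogene):
        src = f"hp-{int(rng.integers(1, cfg.n_mirna + 1))}"
        seq = list(hairpins[src])
        for _ in range(int(rng.integers(3, 6))):
            pos = int(rng.integers(len(seq)))
            seq[pos] = rng.choice([b for b in "ACGT" if b != seq[pos]])
        cursor += int(rng.integers(2000, 8000))
        if cursor + len(seq) > cfg.genome_length - 100:
            raise ValueError("requested feature counts exceed genome capacity")
        rid = f"pseudo-{i + 1}"
        pseudogenes[rid] = "".join(seq)
        genome_list[cursor:cursor + len(seq)] = seq
        placements[rid] = [(chrom, cursor, cursor + len(seq), "+")]
        cursor += len(seq)
    genome = "".join(genome_list)

    # unannotated transcribed loci: genome-only, absent from every
    # transcript stratum, discovered downstream from pooled coverage
    unannotated: dict[str, tuple[str, int, int]] = {}
    for i in range(cfg.n_unannotated):
        length = int(rng.integers(50, 80))
        cursor += int(rng.integers(2000, 8000))
        if cursor + length > cfg.genome_length - 100:
            raise ValueError("requested feature counts exceed genome capacity")
        unannotated[f"ux-{i + 1}"] = (chrom, cursor, cursor + length)
        cursor += length

    rna_ids = list(arms) + list(ncrna) + list(unannotated)
    conservation = pd.Series(rng.normal(2.0, 2.0, size=len(rna_ids)),
                             index=rna_ids, name="conservation")

    n_dnase = max(5, cfg.genome_length // 10_000)
    starts = np.sort(rng.integers(0, cfg.genome_length - 1200, size=n_dnase))
    dnase = [(chrom, int(s), int(s + rng.integers(200, 1000))) for s in starts]

    return Catalogue(genome={chrom: genome}, hairpins=hairpins, arms=arms,
                     ncrna=ncrna, pseudogenes=pseudogenes,
                     placements=placements, clusters=clusters,
                     conservation=conservation, dnase_track=dnase,
                     unannotated=unannotated)


@dataclass
class Cohort:
    """Ground truth of a simulated cohort."""

    samples: list[str]
    covariates: pd.DataFrame               # age, batch, tag per sample
    genotypes: pd.DataFrame                # SNP x sample dosages
    snp_info: pd.DataFrame                 # chrom, pos, maf, info per SNP
    variant_genotypes: pd.DataFrame        # variant site x sample (0/1/2)
    true_log2: pd.DataFrame                # RNA x sample expected log2 level
    molecule_counts: pd.DataFrame          # RNA x sample true molecule counts
    phenotypes: pd.DataFrame
    pheno_coefficients: pd.DataFrame

    def pool_of(self, sample: str) -> str:
        return str(self.covariates.loc[sample, "batch"])

    def tag_of(self, sample: str) -> str:
        return str(self.covariates.loc[sample, "tag"])


def _rna_type(rna_id: str) -> str:
    if rna_id.endswith("-5p"):
        return "mature"
    if rna_id.endswith("-3p"):
        return "star"
    if rna_id.startswith("sno-"):
        return "snorna"
    return "other"


def simulate_cohort(catalogue: Catalogue, cfg: SimConfig) -> Cohort:
    """Draw genotypes, expression, molecule counts, covariates, phenotypes.

    log2 expected expression = baseline + sum(beta * dosage) + batch effect
    + noise; genotypes are Hardy-Weinberg at the configured frequencies;
    phenotypes are linear combinations of standardised true RNA levels plus
    noise.
    """
    rng = cfg.rng(2)
    n = cfg.n_samples
    samples = [f"S{i + 1:03d}" for i in range(n)]
    n_tags = len(cfg.tag_set)
    batches = [f"B{i // n_tags + 1}" for i in range(n)]
    tags = [cfg.tag_set[i % n_tags] for i in range(n)]
    covariates = pd.DataFrame({
        "age": rng.integers(40, 71, size=n).astype(float),
        "batch": batches, "tag": tags}, index=samples)

    rna_ids = catalogue.rna_ids()
    known = set(rna_ids)
    for rna, snp, _ in cfg.eqtl_effects:
        if rna not in known:
            raise KeyError(f"eQTL effect refers to unknown RNA {rna!r}")
    for rna, trait, _ in cfg.pheno_links:
        if rna not in known:
            raise KeyError(f"phenotype link refers to unknown RNA {rna!r}")
    for rna, *_ in cfg.edit_sites:
        if rna not in known:
            raise KeyError(f"edit site refers to unknown RNA {rna!r}")
    for rna, *_ in cfg.variant_sites:
        if rna not in known:
            raise KeyError(f"variant site refers to unknown RNA {rna!r}")

    annotations = catalogue.annotations()
    chrom = annotations["chrom"].iloc[0]

    # SNPs: one per planted eQTL effect (placed in cis), plus null SNPs
    snp_rows, geno = {}, {}
    for rna, snp, beta in cfg.eqtl_effects:
        if snp not in snp_rows:
            ann = annotations.loc[rna]
            pos = int(ann["start"]) + int(rng.integers(-50_000, 50_000))
            pos = max(0, min(cfg.genome_length - 1, pos))
            maf = 0.3
            snp_rows[snp] = (chrom, pos, maf, 0.99)
            geno[snp] = rng.binomial(2, maf, size=n).astype(float)
    for i in range(cfg.n_null_snps):
        snp = f"null-snp-{i + 1}"
        pos = int(rng.integers(0, cfg.genome_length))
        maf = float(rng.uniform(0.05, 0.5))
        snp_rows[snp] = (chrom, pos, maf, float(rng.uniform(0.85, 1.0)))
        geno[snp] = rng.binomial(2, maf, size=n).astype(float)
    snp_info = pd.DataFrame.from_dict(
        snp_rows, orient="index", columns=["chrom", "pos", "maf", "info"])
    genotypes = pd.DataFrame(geno, index=samples).T

    variant_geno = {}
    for rna, offset, ref, alt, af in cfg.variant_sites:
        variant_geno[f"{rna}:{offset}"] = rng.binomial(2, af, size=n)
    variant_genotypes = pd.DataFrame(variant_geno, index=samples).T

    base = {r: rng.normal(cfg.baseline_log2[_rna_type(r)], cfg.baseline_sd)
            for r in rna_ids}
    batch_levels = sorted(set(batches))
    batch_eff = {(r, b): rng.normal(0.0, cfg.batch_sd)
                 for r in rna_ids for b in batch_levels}
    expr = np.zeros((len(rna_ids), n))
    for gi, r in enumerate(rna_ids):
        row = np.full(n, base[r])
        for rna, snp, beta in cfg.eqtl_effects:
            if rna == r:
                row = row + beta * genotypes.loc[snp].to_numpy()
        row = row + np.array([batch_eff[(r, b)] for b in batches])
        row = row + rng.normal(0.0, cfg.noise_sd, size=n)
        expr[gi] = row
    true_log2 = pd.DataFrame(expr, index=rna_ids, columns=samples)

    depth = rng.poisson(cfg.read_depth_mean, size=n)
    n_contam = rng.binomial(depth, cfg.contaminant_fraction)
    n_rna_reads = depth - n_contam
    probs = np.power(2.0, expr)
    probs = probs / probs.sum(axis=0, keepdims=True)
    counts = np.zeros((len(rna_ids), n), dtype=np.int64)
    for j in range(n):
        counts[:, j] = rng.multinomial(int(n_rna_reads[j]), probs[:, j])
    molecule_counts = pd.DataFrame(counts, index=rna_ids, columns=samples)
    molecule_counts.attrs["n_contaminant"] = {
        s: int(c) for s, c in zip(samples, n_contam)}

    traits = sorted(cfg.pheno_noise)
    pheno = {}
    coeff_rows = []
    z = {r: (true_log2.loc[r] - true_log2.loc[r].mean())
         / max(true_log2.loc[r].std(), 1e-9) for r in rna_ids}
    for trait in traits:
        vals = np.full(n, cfg.pheno_base[trait])
        for rna, t, beta in cfg.pheno_links:
            if t == trait:
                vals = vals + beta * z[rna].to_numpy()
                coeff_rows.append((trait, rna, beta))
        vals = vals + rng.normal(0.0, cfg.pheno_noise[trait], size=n)
        pheno[trait] = vals
    phenotypes = pd.DataFrame(pheno, index=samples)
    pheno_coefficients = pd.DataFrame(coeff_rows,
                                      columns=["trait", "rna", "beta"])

    return Cohort(samples=samples, covariates=covariates, genotypes=genotypes,
                  snp_info=snp_info, variant_genotypes=variant_genotypes,
                  true_log2=true_log2, molecule_counts=molecule_counts,
                  phenotypes=phenotypes, pheno_coefficients=pheno_coefficients)


def variant_site_list(catalogue: Catalogue, cfg: SimConfig) -> list[VariantSite]:
    """Reference-space variant sites (hairpin / ncRNA and genome) derived
    from the configured RNA-space variants, for IUPAC reference building."""
    sites: list[VariantSite] = []
    for rna, offset, ref, alt, af in cfg.variant_sites:
        if rna in catalogue.arms:
            hp, start, end = catalogue.arms[rna]
            hp_off = start + offset
            sites.append(VariantSite(hp, hp_off, ref, (alt,), af))
            chrom, hstart, _, _ = catalogue.placements[hp][0]
            sites.append(VariantSite(chrom, hstart + hp_off, ref, (alt,), af))
        else:
            sites.append(VariantSite(rna, offset, ref, (alt,), af))
            chrom, rstart, _, _ = catalogue.placements[rna][0]
            sites.append(VariantSite(chrom, rstart + offset, ref, (alt,), af))
    return sites


def synthesize_reads(cohort: Cohort, catalogue: Catalogue, cfg: SimConfig):
    """Emit pooled tagged reads plus a per-read truth sidecar.

    Returns ``(reads_by_pool, sidecar)``.  Each read is six-base tag + RNA
    sequence (genotype-consistent alleles, edits at the configured per-read
    rates, substitution errors) + 3' adapter, truncated to 37 bases.
    Contaminant reads are tag + linker + adapter (adapter-ligation products
    carrying no RNA insert).
    """
    rng = cfg.rng(3)
    var_by_rna: dict[str, list] = {}
    for rna, offset, ref, alt, af in cfg.variant_sites:
        var_by_rna.setdefault(rna, []).append((offset, ref, alt))
    edit_by_rna: dict[str, list] = {}
    for rna, offset, rate in cfg.edit_sites:
        edit_by_rna.setdefault(rna, []).append((offset, rate))

    reads_by_pool: dict[str, list[ReadRecord]] = {}
    sidecar_rows = []
    read_no = 0
    bases = np.array(list("ACGT"))
    for sample in cohort.samples:
        pool = cohort.pool_of(sample)
        tag = cohort.tag_of(sample)
        pool_reads = reads_by_pool.setdefault(pool, [])
        for rna, count in cohort.molecule_counts[sample].items():
            if count == 0:
                continue
            if rna in catalogue.arms:
                base_seq = catalogue.arm_sequence(rna)
            elif rna in catalogue.unannotated:
                chrom, ustart, uend = catalogue.unannotated[rna]
                base_seq = catalogue.genome[chrom][ustart:ustart
                                                   + min(22, uend - ustart)]
            else:
                full = catalogue.ncrna[rna]
                base_seq = full[:31]        # size-selected fragment
            variants = var_by_rna.get(rna, [])
            edits = edit_by_rna.get(rna, [])
            for _ in range(int(count)):
                seq = list(base_seq)
                alleles = []
                for offset, ref, alt in variants:
                    g = int(cohort.variant_genotypes.loc[f"{rna}:{offset}",
                                                         sample])
                    use_alt = (g == 2) or (g == 1 and rng.random() < 0.5)
                    if use_alt and offset < len(seq):
                        seq[offset] = alt
                    alleles.append(alt if use_alt else ref)
                edited = []
                for offset, rate in edits:
                    hit = rng.random() < rate
                    if hit and offset < len(seq):
                        seq[offset] = "G"
                    edited.append(offset if hit else -1)
                n_err = rng.binomial(len(seq), cfg.error_rate)
                for pos in rng.choice(len(seq), size=n_err, replace=False):
                    cur = seq[pos]
                    seq[pos] = str(rng.choice(bases[bases != cur]))
                insert = "".join(seq)
                read_seq = (tag + insert + cfg.adapter3)[:READ_LENGTH]
                read_no += 1
                rid = f"r{read_no:08d}"
                pool_reads.append(ReadRecord(rid, read_seq,
                                             "I" * len(read_seq)))
                sidecar_rows.append((rid, sample, pool, tag, rna,
                                     ";".join(map(str, edited)) or "",
                                     ";".join(alleles), int(n_err)))
        for _ in range(cohort.molecule_counts.attrs["n_contaminant"][sample]):
            read_seq = (tag + cfg.linker + cfg.adapter3)[:READ_LENGTH]
            read_no += 1
            rid = f"r{read_no:08d}"
            pool_reads.append(ReadRecord(rid, read_seq, "I" * len(read_seq)))
            sidecar_rows.append((rid, sample, pool, tag, "contaminant",
                                 "", "", 0))
    sidecar = pd.DataFrame(sidecar_rows, columns=[
        "read_id", "sample", "pool", "tag", "source", "edited_offsets",
        "alleles", "n_errors"]).set_index("read_id")
    return reads_by_pool, sidecar


def simulate_mrna_matrix(cohort: Cohort, catalogue: Catalogue, cfg: SimConfig,
                         target_mirna: str | None = None,
                         n_targets: int = 200, n_background: int = 300,
                         coupling: float = -0.5, utr_length: int = 500):
    """mRNA probe expression and 3'UTR sequences with planted seed targets.

    Target probes carry the seed-complementary 8-mer of ``target_mirna`` in
    their UTR and their expression is coupled to the miRNA with coefficient
    ``coupling`` (on standardised scales); background probes have matched
    base composition.  Returns (mrna_expr, utr_seqs dict, seed family).
    """
    from .seeds import SeedFamily

    rng = cfg.rng(4)
    if target_mirna is None:
        target_mirna = next(iter(catalogue.arms))
    fam = SeedFamily.from_mirna(catalogue.arm_sequence(target_mirna))
    mir = cohort.true_log2.loc[target_mirna]
    mir_z = (mir - mir.mean()) / max(mir.std(), 1e-9)

    probes, utrs, rows = [], {}, []
    for i in range(n_targets + n_background):
        probe = f"probe-{i + 1}"
        utr = list(rng.choice(list("ACGT"), size=utr_length))
        is_target = i < n_targets
        if is_target:
            pos = int(rng.integers(0, utr_length - 8))
            utr[pos:pos + 8] = list(fam.s8)
        utrs[probe] = "".join(utr)
        z = rng.normal(0.0, 1.0, size=len(cohort.samples))
        if is_target:
            vals = coupling * mir_z.to_numpy() + z
        else:
            vals = z
        probes.append(probe)
        rows.append(vals)
    mrna_expr = pd.DataFrame(rows, index=probes, columns=cohort.samples)
    targets = probes[:n_targets]
    return mrna_expr, utrs, fam, targets


def choose_edit_sites(catalogue: Catalogue, rates=(0.25, 0.18, 0.11),
                      offsets=(6, 7, 8)) -> list[tuple[str, int, float]]:
    """Pick editable adenosines in mature seed regions.

    Emulates edits at the 7th-9th bases of mature products: for each
    requested rate, the first unused mature arm with an A at the paired
    offset is chosen.
    """
    out = []
    used = set()
    for rate, offset in zip(rates, offsets):
        for arm_id in catalogue.arms:
            if arm_id in used or not arm_id.endswith("-5p"):
                continue
            seq = catalogue.arm_sequence(arm_id)
            if offset < len(seq) - 2 and seq[offset] == "A":
                out.append((arm_id, offset, rate))
                used.add(arm_id)
                break
    return out


def choose_variant_sites(catalogue: Catalogue, n: int = 3, af: float = 0.11,
                         seed: int = 0) -> list[tuple[str, int, str, str, float]]:
    """Pick planted polymorphic sites in mature/snoRNA products.

    The reference base is read from the catalogue; the alternate allele is a
    deterministic substitution.  Sites avoid the last two bases of the
    product (the degradation-artefact zone) and the seed offsets used for
    editing.
    """
    rng = np.random.default_rng([seed, 6])
    out = []
    arm_ids = [a for a in catalogue.arms if a.endswith("-5p")]
    sno_ids = list(catalogue.ncrna)
    pool = arm_ids[:1] + sno_ids[:max(0, n - 1)] if n > 1 else arm_ids[:n]
    for rna in pool[:n]:
        if rna in catalogue.arms:
            seq = catalogue.arm_sequence(rna)
        else:
            seq = catalogue.ncrna[rna][:31]
        offset = int(rng.integers(10, max(11, len(seq) - 3)))
        ref = seq[offset]
        alt = {"A": "C", "C": "T", "G": "T", "T": "G"}[ref]
        out.append((rna, offset, ref, alt, af))
    return out


def planted_config(seed: int = 0, n_eqtl: int = 3, eqtl_beta: float = 1.0,
                   **kwargs) -> tuple[SimConfig, Catalogue]:
    """A SimConfig with planted eQTLs, edits, variants and phenotype links
    wired to the catalogue the same seed generates.

    The catalogue depends only on the seed and size parameters, so it is
    built once from a skeleton config and the effect lists are filled in
    against its RNA ids.
    """
    skeleton = SimConfig(seed=seed, **kwargs)
    catalogue = make_reference_catalogue(skeleton)
    arm_ids = [a for a in catalogue.arms if a.endswith("-5p")]
    eqtls = [(arm_ids[i], f"eqtl-snp-{i + 1}", eqtl_beta)
             for i in range(min(n_eqtl, len(arm_ids)))]
    edits = choose_edit_sites(catalogue)
    variants = choose_variant_sites(catalogue, seed=seed)
    linked = arm_ids[n_eqtl:n_eqtl + 3]
    links = []
    for trait in ("bmi", "ptfm", "insulin"):
        for j, rna in enumerate(linked):
            links.append((rna, trait, 2.0 - 0.5 * j))
    cfg = SimConfig(seed=seed, eqtl_effects=eqtls, edit_sites=edits,
                    variant_sites=variants, pheno_links=links, **kwargs)
    return cfg, catalogue


def simulate_dna_pileups(cohort: Cohort, cfg: SimConfig,
                         n_dna_samples: int | None = None,
                         mean_depth: float = 30.0):
    """DNA read pileups at the planted variant and edit sites for a subset
    of samples (emulating whole-genome sequencing of part of the cohort).

    Variant sites show the sample's true alleles; edit sites are homozygous
    reference in DNA.  Returns {site key: {sample: length-4 ACGT counts}}.
    """
    rng = cfg.rng(5)
    if n_dna_samples is None:
        n_dna_samples = max(2, int(0.3 * len(cohort.samples)))
    dna_samples = list(cohort.samples[:n_dna_samples])
    base_index = {b: i for i, b in enumerate("ACGT")}
    out: dict[str, dict[str, np.ndarray]] = {}
    for rna, offset, ref, alt, af in cfg.variant_sites:
        key = f"{rna}:{offset}"
        site = out.setdefault(key, {})
        for s in dna_samples:
            g = int(cohort.variant_genotypes.loc[key, s])
            depth = int(rng.poisson(mean_depth))
            n_alt = int(rng.binomial(depth, g / 2.0)) if depth else 0
            counts = np.zeros(4, dtype=np.int64)
            counts[base_index[ref]] = depth - n_alt
            counts[base_index[alt]] += n_alt
            site[s] = counts
    for rna, offset, rate in cfg.edit_sites:
        key = f"{rna}:{offset}"
        site = out.setdefault(key, {})
        for s in dna_samples:
            depth = int(rng.poisson(mean_depth))
            counts = np.zeros(4, dtype=np.int64)
            counts[base_index["A"]] = depth
            site[s] = counts
    return out, dna_samples
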
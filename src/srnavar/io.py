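"""File formats: FASTA/FASTQ via Biopython, tables as TSV, intervals as BED.

Coordinates are 0-based half-open in memory; BED-adjacent text output is
written 1-based inclusive (documented convention of this package).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .demux import ReadRecord


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(path, reads) -> None:
    def records():
        for r in reads:
            rec = SeqRecord(Seq(r.seq), id=r.id, description="")
            rec.letter_annotations["phred_quality"] = [
                ord(q) - 33 for q in r.qual]
            yield rec
    SeqIO.write(records(), str(path), "fastq")


def read_fastq(path):
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        yield ReadRecord(rec.id, str(rec.seq).upper(),
                         "".join(chr(q + 33) for q in quals))


def write_table(path, frame: pd.DataFrame, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_bed(path, intervals) -> None:
    """Write (chrom, start, end[, name...]) intervals as 1-based inclusive
    text (half-open inputs)."""
    with open(path, "w") as fh:
        for iv in intervals:
            chrom, start, end, *rest = iv
            fields = [str(chrom), str(int(start) + 1), str(int(end))]
            fields.extend(str(x) for x in rest)
            fh.write("\t".join(fields) + "\n")


def read_bed(path):
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            out.append((parts[0], int(parts[1]) - 1, int(parts[2]),
                        *parts[3:]))
    return out


def write_catalogue(outdir, catalogue) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(out / "genome.fasta", catalogue.genome)
    write_fasta(out / "hairpins.fasta", catalogue.hairpins)
    write_fasta(out / "ncrna.fasta", catalogue.ncrna)
    write_fasta(out / "pseudogenes.fasta", catalogue.pseudogenes)
    arms = pd.DataFrame(
        [(a, hp, s, e) for a, (hp, s, e) in catalogue.arms.items()],
        columns=["arm_id", "hairpin", "start", "end"])
    write_table(out / "arms.tsv", arms, index=False)
    placements = pd.DataFrame(
        [(rid, c, s, e, st) for rid, plist in catalogue.placements.items()
         for c, s, e, st in plist],
        columns=["seq_id", "chrom", "start", "end", "strand"])
    write_table(out / "placements.tsv", placements, index=False)
    clusters = pd.DataFrame(
        [(cid, m) for cid, members in catalogue.clusters.items()
         for m in members], columns=["cluster_id", "hairpin"])
    write_table(out / "clusters.tsv", clusters, index=False)
    write_table(out / "conservation.tsv", catalogue.conservation.to_frame())
    write_bed(out / "dnase.bed", catalogue.dnase_track)


def read_catalogue(indir):
    from .simulate import Catalogue
    ind = Path(indir)
    arms_df = pd.read_csv(ind / "arms.tsv", sep="\t")
    placements_df = pd.read_csv(ind / "placements.tsv", sep="\t")
    placements: dict[str, list] = {}
    for row in placements_df.itertuples():
        placements.setdefault(row.seq_id, []).append(
            (row.chrom, int(row.start), int(row.end), row.strand))
    clusters_df = pd.read_csv(ind / "clusters.tsv", sep="\t")
    clusters: dict[str, list] = {}
    for row in clusters_df.itertuples():
        clusters.setdefault(row.cluster_id, []).append(row.hairpin)
    return Catalogue(
        genome=read_fasta(ind / "genome.fasta"),
        hairpins=read_fasta(ind / "hairpins.fasta"),
        ncrna=read_fasta(ind / "ncrna.fasta"),
        pseudogenes=read_fasta(ind / "pseudogenes.fasta"),
        arms={r.arm_id: (r.hairpin, int(r.start), int(r.end))
              for r in arms_df.itertuples()},
        placements=placements, clusters=clusters,
        conservation=pd.read_csv(ind / "conservation.tsv", sep="\t",
                                 index_col=0)["conservation"],
        dnase_track=[(c, s, e) for c, s, e, *_ in read_bed(ind / "dnase.bed")])


def write_strata(outdir, strata) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, stratum in strata.items():
        write_fasta(out / f"{name}.fasta", stratum.sequences)


def read_strata(indir):
    from .references import ReferenceStratum, STRATUM_RANKS
    ind = Path(indir)
    out = {}
    for name in STRATUM_RANKS:
        path = ind / f"{name}.fasta"
        if path.exists():
            out[name] = ReferenceStratum(name, read_fasta(path))
    return out
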
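"""File formats: reference FASTA+JSON sidecar, guides, FASTQ, pileups, SAM.

All tabular outputs are plain TSV; FASTQ may be gzipped (detected by
suffix).  The reference travels as a single-record FASTA plus a JSON
sidecar carrying what FASTA cannot: contig, genomic anchor and coding
frame.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError
from .phasing import EditSite, GermlineSite, PhasingSites, PhasingResult
from .quantify import PILEUP_COLUMNS, Pileup, SampleQuant
from .reference import AmpliconReference, CodingFrame, GuideDesign, encode
from .simulate import FastqRead, SimulatedClone


# --- reference -------------------------------------------------------------

def write_reference(ref: AmpliconReference, fasta_path: Path | str,
                    meta_path: Optional[Path | str] = None) -> None:
    fasta_path = Path(fasta_path)
    meta_path = Path(meta_path) if meta_path else fasta_path.with_suffix(".json")
    record = SeqRecord(Seq(ref.sequence), id=ref.name, description="")
    with open(fasta_path, "w") as fh:
        SeqIO.write([record], fh, "fasta")
    meta = {"contig": ref.contig, "genomic_start": ref.genomic_start}
    if ref.coding_frame is not None:
        meta["coding_frame"] = {
            "frame_offset": ref.coding_frame.frame_offset,
            "coding_strand": ref.coding_frame.strand,
        }
    meta_path.write_text(json.dumps(meta, indent=2))


def read_reference(fasta_path: Path | str,
                   meta_path: Optional[Path | str] = None) -> AmpliconReference:
    fasta_path = Path(fasta_path)
    meta_path = Path(meta_path) if meta_path else fasta_path.with_suffix(".json")
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValidationError(f"{fasta_path} must hold exactly one record, found {len(records)}")
    meta = json.loads(Path(meta_path).read_text())
    frame = None
    if "coding_frame" in meta and meta["coding_frame"] is not None:
        frame = CodingFrame(
            frame_offset=int(meta["coding_frame"]["frame_offset"]),
            strand=meta["coding_frame"].get("coding_strand", "+"),
        )
    return AmpliconReference(
        name=records[0].id,
        contig=meta["contig"],
        genomic_start=int(meta["genomic_start"]),
        sequence=str(records[0].seq),
        coding_frame=frame,
    )


# --- guides ----------------------------------------------------------------

def write_guides(guides: Sequence[GuideDesign], path: Path | str) -> None:
    payload = [
        {
            "guide_id": g.guide_id,
            "protospacer": g.protospacer,
            "strand": g.strand,
            "anchor": g.anchor,
            "target_position": g.target_position,
            "window": list(g.window),
            "contig": g.contig,
        }
        for g in guides
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_guides(path: Path | str) -> list[GuideDesign]:
    path = Path(path)
    if path.suffix.lower() in (".tsv", ".txt"):
        df = pd.read_csv(path, sep="\t")
        payload = df.to_dict("records")
        for row in payload:
            if isinstance(row.get("window"), str):
                lo, hi = row["window"].split("-")
                row["window"] = [int(lo), int(hi)]
    else:
        payload = json.loads(path.read_text())
    return [
        GuideDesign(
            guide_id=str(row["guide_id"]),
            protospacer=str(row["protospacer"]),
            strand=str(row["strand"]),
            anchor=int(row["anchor"]),
            target_position=int(row["target_position"]),
            window=tuple(row.get("window", (4, 7))),
            contig=str(row.get("contig", "")),
        )
        for row in payload
    ]


# --- FASTQ -----------------------------------------------------------------

def _open_text(path: Path | str, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def iter_fastq(path: Path | str) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality) from a possibly gzipped FASTQ."""
    with _open_text(path) as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq(reads: Iterable[FastqRead | tuple[str, str, str]], path: Path | str) -> None:
    """Write records to FASTQ (gzipped when the path ends in .gz)."""
    with _open_text(path, "wt") as fh:
        for title, seq, qual in reads:
            fh.write(f"@{title}\n{seq}\n+\n{qual}\n")


def write_clone_fastq(clone: SimulatedClone, outdir: Path | str,
                      gzipped: bool = True) -> tuple[Path, Path, Path]:
    """Write a simulated clone's R1/R2 plus its ground-truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = ".fastq.gz" if gzipped else ".fastq"
    r1 = outdir / f"{clone.clone_id}_R1{ext}"
    r2 = outdir / f"{clone.clone_id}_R2{ext}"
    manifest = outdir / f"{clone.clone_id}.manifest.json"
    write_fastq(clone.r1, r1)
    write_fastq(clone.r2, r2)
    manifest.write_text(json.dumps(clone.manifest(), indent=2))
    return r1, r2, manifest


# --- pileups ---------------------------------------------------------------

def write_pileup(quant: SampleQuant, path: Path | str) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sample_id={quant.sample_id}\n")
        fh.write(f"# ref_name={quant.ref_name}\n")
        fh.write(f"# contig={quant.contig}\n")
        fh.write(f"# genomic_start={quant.genomic_start}\n")
        fh.write(f"# ref_sequence={''.join('ACGT'[c] for c in quant.ref_codes)}\n")
        fh.write(
            f"# n_fragments={quant.n_fragments} n_mapped={quant.n_mapped_fragments} "
            f"n_unmapped_reads={quant.n_unmapped_reads}\n"
        )
        quant.to_dataframe().to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_pileup(path: Path | str) -> SampleQuant:
    path = Path(path)
    header: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            for token in line[1:].strip().split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    header[k] = v
        else:
            body_start = i
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
    counts = df[list(PILEUP_COLUMNS)].to_numpy(dtype=np.int64)
    pileup = Pileup(counts=counts, insertion_starts=df["ins"].to_numpy(dtype=np.int64))
    return SampleQuant(
        sample_id=header.get("sample_id", path.stem),
        ref_name=header.get("ref_name", ""),
        contig=header.get("contig", ""),
        genomic_start=int(header.get("genomic_start", df["position"].iloc[0])),
        ref_codes=encode(header["ref_sequence"]),
        pileup=pileup,
        n_fragments=int(header.get("n_fragments", 0)),
        n_mapped_fragments=int(header.get("n_mapped", 0)),
        n_unmapped_reads=int(header.get("n_unmapped_reads", 0)),
    )


# --- SAM -------------------------------------------------------------------

def quantify_sample_from_sam(
    path: Path | str,
    ref: AmpliconReference,
    sample_id: str = "sample",
    quality_floor: int = 20,
) -> SampleQuant:
    """Build a pileup from pre-aligned reads in SAM/BAM.

    Mates are *not* re-reconciled here: the caller's aligner already placed
    each read, and each mapped read contributes its aligned bases subject to
    the quality floor.  Coordinates in the SAM must be against the amplicon
    itself (as produced by an amplicon-targeted mapper run).
    """
    import pysam

    from .errors import EmptySampleError

    pileup = Pileup.empty(len(ref))
    n_reads = n_mapped = 0
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for read in fh.fetch(until_eof=True):
            if read.is_unmapped or read.query_sequence is None:
                n_reads += 1
                continue
            n_reads += 1
            n_mapped += 1
            seq = read.query_sequence
            quals = read.query_qualities
            positions: list[int] = []
            codes: list[int] = []
            for qpos, rpos in read.get_aligned_pairs():
                if rpos is None or rpos >= len(ref):
                    continue
                if qpos is None:
                    positions.append(rpos)
                    codes.append(4)
                else:
                    if quals is not None and quals[qpos] < quality_floor:
                        continue
                    base = seq[qpos].upper()
                    if base in "ACGT":
                        positions.append(rpos)
                        codes.append("ACGT".index(base))
            np.add.at(pileup.counts, (np.array(positions, int), np.array(codes, int)), 1)
    if n_mapped == 0:
        raise EmptySampleError(f"sample {sample_id!r}: no mapped reads in {path}")
    return SampleQuant(
        sample_id=sample_id,
        ref_name=ref.name,
        contig=ref.contig,
        genomic_start=ref.genomic_start,
        ref_codes=ref.codes,
        pileup=pileup,
        n_fragments=n_reads,
        n_mapped_fragments=n_mapped,
        n_unmapped_reads=n_reads - n_mapped,
    )


# --- phasing ---------------------------------------------------------------

def read_sites(path: Path | str) -> PhasingSites:
    d = json.loads(Path(path).read_text())
    return PhasingSites(
        edit_site=EditSite(
            position=int(d["edit_site"]["position"]),
            ref=d["edit_site"]["ref"],
            alt=d["edit_site"]["alt"],
        ),
        germline_site=GermlineSite(
            position=int(d["germline_site"]["position"]),
            allele1=d["germline_site"]["allele1"],
            allele2=d["germline_site"]["allele2"],
        ),
    )


def write_sites(sites: PhasingSites, path: Path | str) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "edit_site": {
                    "position": sites.edit_site.position,
                    "ref": sites.edit_site.ref,
                    "alt": sites.edit_site.alt,
                },
                "germline_site": {
                    "position": sites.germline_site.position,
                    "allele1": sites.germline_site.allele1,
                    "allele2": sites.germline_site.allele2,
                },
            },
            indent=2,
        )
    )


def write_phasing_report(result: PhasingResult, sites: PhasingSites, path: Path | str) -> None:
    payload = {
        "edit_site": sites.edit_site.position,
        "germline_site": sites.germline_site.position,
        "distance_bp": sites.expected_distance,
        "joint_counts": {
            "ref_allele1": int(result.joint_counts[0, 0]),
            "ref_allele2": int(result.joint_counts[0, 1]),
            "alt_allele1": int(result.joint_counts[1, 0]),
            "alt_allele2": int(result.joint_counts[1, 1]),
        },
        "informative_fragments": result.informative_fragments,
        "uninformative_fragments": result.uninformative_fragments,
        "phase_call": result.phase_call,
        "purity": result.purity,
        "germline_balance": result.germline_balance,
        "edit_fraction": result.edit_fraction,
        "monoclonal": result.monoclonal,
        "diagnostics": list(result.diagnostics),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
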
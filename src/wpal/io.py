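"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA goes through Biopython; BED/TSV/GFF3 are thin pandas/text layers.
All interval files are 0-based half-open (BED convention) except where a
report explicitly states 1-based inclusive coordinates.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_bed(path: str | Path, intervals: list[tuple]) -> None:
    """Write (chrom, start, end[, name[, score]]) tuples as BED."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


def write_depth_tsv(path: str | Path, track) -> None:
    track.to_frame().to_csv(path, sep="\t", index=False)


def read_depth_tsv(path: str | Path):
    from .synthetic_data import DepthTrack

    df = pd.read_csv(path, sep="\t")
    chrom = df["chrom"].iloc[0] if len(df) else "unknown"
    return DepthTrack(chrom=chrom, depth=df["depth"].to_numpy(), start=int(df["pos"].iloc[0]) if len(df) else 0)


def write_gbs_tsv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_gbs_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ltr_gff3(path: str | Path, chrom: str, elements) -> None:
    """GFF3 with LTR_retrotransposon / long_terminal_repeat / target_site_duplication rows."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for el in elements:
            s, e = el.five_prime[0], el.three_prime[1]
            attrs = f"ID={el.element_id};tsd={el.tsd}"
            if el.true_age is not None:
                attrs += f";true_age={el.true_age:g}"
            fh.write(
                f"{chrom}\twpal\tLTR_retrotransposon\t{s + 1}\t{e}\t.\t+\t.\t{attrs}\n"
            )
            for tag, (a, b) in (("five_prime", el.five_prime), ("three_prime", el.three_prime)):
                fh.write(
                    f"{chrom}\twpal\tlong_terminal_repeat\t{a + 1}\t{b}\t.\t+\t.\t"
                    f"ID={el.element_id}.{tag};Parent={el.element_id}\n"
                )
            fh.write(
                f"{chrom}\twpal\ttarget_site_duplication\t{s - len(el.tsd) + 1}\t{s}\t.\t+\t.\t"
                f"Parent={el.element_id}\n"
            )


def read_sites_tsv(path: str | Path) -> pd.DataFrame:
    """Pileup-summary site table (pos, ref, alt, qual, depth, per-species depths)."""
    return pd.read_csv(path, sep="\t")


def read_sites_vcf(path: str | Path) -> pd.DataFrame:
    """Minimal VCF reader for collapsed-arm variant sites.

    Expects INFO keys DPA_REF/DPA_ALT/DPB_REF/DPB_ALT carrying per-species
    reference and alternate depths; DP is read from INFO or recomputed.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _id, ref, alt, qual, _filt, info = line.rstrip("\n").split("\t")[:8]
            kv = dict(
                item.split("=", 1) for item in info.split(";") if "=" in item
            )
            a_ref = int(kv.get("DPA_REF", 0))
            a_alt = int(kv.get("DPA_ALT", 0))
            rows.append(
                {
                    "pos": int(pos) - 1,
                    "ref": ref,
                    "alt": alt,
                    "qual": float(qual) if qual != "." else 0.0,
                    "depth": int(kv.get("DP", a_ref + a_alt)),
                    "depth_A_ref": a_ref,
                    "depth_A_alt": a_alt,
                    "depth_B_ref": int(kv.get("DPB_REF", 0)),
                    "depth_B_alt": int(kv.get("DPB_ALT", 0)),
                }
            )
    return pd.DataFrame(rows)


def write_protein_fasta(path: str | Path, proteins: dict[str, str]) -> None:
    write_fasta(path, proteins)
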
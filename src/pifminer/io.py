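"""Readers/writers for the package's on-disk formats.

FASTA via Biopython (80-column wrap); element calls as GFF3
``mobile_genetic_element`` features and BED6; tables as TSV via pandas.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

if TYPE_CHECKING:  # pragma: no cover
    from .classify import ElementAnnotation
    from .mining import TIRHit
    from .synthetic import PlantedTruth


def write_fasta(scaffolds: Mapping[str, str], path: str, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in scaffolds.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_truth_tsv(truths: Iterable["PlantedTruth"], path: str) -> None:
    rows = [
        {
            "element_id": t.element_id,
            "scaffold": t.scaffold_id,
            "class": t.class_name,
            "family": t.family,
            "start": t.start,
            "end": t.end,
            "tsd": t.tsd,
        }
        for t in truths
    ]
    pd.DataFrame(
        rows, columns=["element_id", "scaffold", "class", "family", "start", "end", "tsd"]
    ).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"tsd": str})


def hits_to_bed6(hits: Iterable["TIRHit"], path: str, name: str = "TIR") -> None:
    with open(path, "w") as fh:
        for h in hits:
            strand = "+" if h.orientation == "forward" else "-"
            fh.write(
                f"{h.scaffold_id}\t{h.start}\t{h.end}\t{name}\t"
                f"{h.mismatches}\t{strand}\n"
            )


def write_elements_gff3(annotations: Iterable["ElementAnnotation"], path: str) -> None:
    """Element calls as 1-based GFF3 ``mobile_genetic_element`` features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            attrs = (
                f"ID={a.element_id};class={a.class_name};"
                f"family={a.family or 'NA'};tsd={a.tsd or 'NNN'};"
                f"tsd_valid={str(a.tsd_valid).lower()}"
            )
            fh.write(
                f"{a.scaffold_id}\tpifminer\tmobile_genetic_element\t"
                f"{a.start + 1}\t{a.end}\t.\t.\t.\t{attrs}\n"
            )


def read_elements_gff3(path: str) -> pd.DataFrame:
    """Element calls back from GFF3 (0-based half-open coordinates)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "mobile_genetic_element":
                continue
            attrs = dict(p.split("=", 1) for p in f[8].split(";") if "=" in p)
            rows.append(
                {
                    "element_id": attrs.get("ID", ""),
                    "scaffold": f[0],
                    "start": int(f[3]) - 1,
                    "end": int(f[4]),
                    "class": attrs.get("class", ""),
                    "family": attrs.get("family", ""),
                    "tsd": attrs.get("tsd", ""),
                    "tsd_valid": attrs.get("tsd_valid", "false") == "true",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "element_id", "scaffold", "start", "end", "class", "family", "tsd",
            "tsd_valid",
        ],
    )
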
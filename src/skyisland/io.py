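"""Readers and writers for the package's plain-text interchange formats.

FASTA for alignments (Biopython), newick for trees (dendropy), and
tab-delimited text for genotype tables, sample metadata and predictor
tables (pandas).  Round-trips are lossless for every format.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dbrda import PredictorTable
from .msat import GenotypeTable
from .seqstats import HaplotypeAlignment

__all__ = [
    "read_fasta_alignment", "write_fasta_alignment",
    "read_metadata", "write_metadata",
    "read_genotypes", "write_genotypes",
    "read_predictors", "write_predictors",
    "read_newick", "write_newick",
    "read_distance_matrix", "write_distance_matrix",
]


def write_fasta_alignment(alignment: HaplotypeAlignment, path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=sid, description="")
               for sid, s in zip(alignment.sample_ids, alignment.sequences)]
    if alignment.outgroup:
        records += [SeqRecord(Seq(s), id=sid, description="outgroup")
                    for sid, s in alignment.outgroup.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta_alignment(path: str | Path,
                         deme_of_sample: dict[str, str]) -> HaplotypeAlignment:
    """Read a FASTA alignment; records described as 'outgroup' are set aside."""
    seqs, ids, outgroup = [], [], {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "outgroup" in rec.description.split()[1:]:
            outgroup[rec.id] = str(rec.seq)
        else:
            ids.append(rec.id)
            seqs.append(str(rec.seq))
    return HaplotypeAlignment(seqs, ids, deme_of_sample, outgroup or None)


def write_metadata(deme_of_sample: dict[str, str],
                   subregion_of_deme: dict[str, str] | None,
                   path: str | Path) -> None:
    rows = [{"sample": s, "deme": d,
             "subregion": (subregion_of_deme or {}).get(d, "")}
            for s, d in deme_of_sample.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    deme_of_sample = dict(zip(df["sample"], df["deme"]))
    sub = {}
    if "subregion" in df.columns:
        sub = {d: s for d, s in zip(df["deme"], df["subregion"]) if s}
    return deme_of_sample, sub


def write_genotypes(table: GenotypeTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_genotypes(path: str | Path) -> GenotypeTable:
    return GenotypeTable.from_frame(pd.read_csv(path, sep="\t", dtype=str))


def write_predictors(table: PredictorTable, path: str | Path) -> None:
    df = table.data.copy()
    # first header line records the set membership so round-trips keep sets
    sets_line = "#sets\t" + "\t".join(
        f"{name}:{','.join(cols)}" for name, cols in table.sets.items())
    with open(path, "w") as fh:
        fh.write(sets_line + "\n")
        df.to_csv(fh, sep="\t", index=True, index_label="location")


def read_predictors(path: str | Path) -> PredictorTable:
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("#sets"):
            raise ValueError("predictor file must start with a '#sets' header line")
        sets = {}
        for item in first.split("\t")[1:]:
            name, cols = item.split(":", 1)
            sets[name] = cols.split(",")
        df = pd.read_csv(fh, sep="\t", index_col="location")
    return PredictorTable(df, sets)


def write_newick(tree_or_string, path: str | Path) -> None:
    text = tree_or_string if isinstance(tree_or_string, str) else \
        tree_or_string.as_string(schema="newick")
    Path(path).write_text(text.rstrip() + "\n")


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def write_distance_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="deme")


def read_distance_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="deme")
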
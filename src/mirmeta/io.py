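"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA goes through Biopython; BED6/BED12 and the TSV tables are simple
tab-separated line formats handled directly (BED12 via ``GeneModel``).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genes import GeneModel


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_bed12(path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith(("#", "track")):
                models.append(GeneModel.from_bed12(line))
    return models


def write_bed12(path, models) -> None:
    with open(path, "w") as fh:
        for m in models:
            fh.write(m.to_bed12() + "\n")


def read_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "start": int, "end": int, "name": str, "strand": str},
    )
    return df


def write_bed6(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=["chrom", "start", "end", "name", "score", "strand"])


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_tsv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index_label=table.index.name or "feature")


def read_log2fc_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def write_log2fc_tsv(path, values: pd.Series, name: str = "log2fc") -> None:
    values.rename(name).to_frame().to_csv(path, sep="\t", index_label="gene_id")


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonify(o):
    try:
        import numpy as np
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
    except Exception:  # pragma: no cover
        pass
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
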
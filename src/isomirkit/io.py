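"""Readers and writers for the pipeline's on-disk formats.

FASTA/FASTQ go through Biopython; tables are plain TSV via pandas.  DE
tables use the three-column header ``gene  log2fc  adj_p``; read pools are
two-column ``sequence  count`` TSVs (or FASTQ with a dummy quality).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file to an id -> sequence map; duplicate ids are an error."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA identifier {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq)
    return out


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_seq_counts(path: str | Path) -> pd.DataFrame:
    """Two-column (sequence, count) TSV; '#'-prefixed lines are comments."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sequence": str, "count": int})
    if list(df.columns) != ["sequence", "count"]:
        raise ValueError(f"expected columns sequence/count in {path}, got {list(df.columns)}")
    return df


def write_seq_counts(path: str | Path, pool: pd.DataFrame) -> None:
    pool[["sequence", "count"]].to_csv(path, sep="\t", index=False)


def read_fastq_counts(path: str | Path) -> pd.DataFrame:
    """Collapse a FASTQ file to distinct-sequence counts."""
    counts: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fastq"):
        s = str(rec.seq)
        counts[s] = counts.get(s, 0) + 1
    return pd.DataFrame(sorted(counts.items()), columns=["sequence", "count"])


def write_fastq(path: str | Path, pool: pd.DataFrame, quality_char: str = "I") -> None:
    """Expand a (sequence, count) pool into FASTQ reads with dummy quality."""
    with open(path, "w") as fh:
        i = 0
        for seq, count in pool[["sequence", "count"]].itertuples(index=False):
            dna = seq.replace("U", "T")
            for _ in range(int(count)):
                i += 1
                fh.write(f"@read{i}\n{dna}\n+\n{quality_char * len(dna)}\n")


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "log2fc", "adj_p"}
    if not required.issubset(df.columns):
        raise ValueError(f"DE table {path} lacks columns {sorted(required - set(df.columns))}")
    return df


def write_de_table(path: str | Path, table: pd.DataFrame) -> None:
    table[["gene", "log2fc", "adj_p"]].to_csv(path, sep="\t", index=False)


def read_mature_coords(path: str | Path) -> pd.DataFrame:
    """Sidecar TSV locating matures in hairpins: name, hairpin_name, start, arm.

    ``start`` is 0-based; the mature interval is half-open.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"name": str, "hairpin_name": str})
    required = {"name", "hairpin_name", "start", "arm"}
    if not required.issubset(df.columns):
        raise ValueError(f"coordinate TSV {path} lacks {sorted(required - set(df.columns))}")
    return df


def read_target_list(path: str | Path) -> set[str]:
    """One-column TSV of gene identifiers (e.g. an imported target list)."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_compendium_dir(directory: str | Path) -> tuple[dict[str, pd.DataFrame], dict]:
    """Directory of DE TSVs plus a ``manifest.json`` naming each study."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    studies = {
        entry["study_id"]: read_de_table(directory / entry["file"])
        for entry in manifest["studies"]
    }
    return studies, manifest


def write_compendium_dir(
    directory: str | Path, studies: Mapping[str, pd.DataFrame], manifest: dict
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for study_id in sorted(studies):
        fname = f"{study_id}.tsv"
        write_de_table(directory / fname, studies[study_id])
        entry = {"study_id": study_id, "file": fname}
        for extra in manifest.get("studies", []):
            if extra.get("study_id") == study_id:
                entry.update(extra)
                entry["file"] = fname
        entries.append(entry)
    out_manifest = {k: v for k, v in manifest.items() if k != "studies"}
    out_manifest["studies"] = entries
    write_json(directory / "manifest.json", out_manifest)
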
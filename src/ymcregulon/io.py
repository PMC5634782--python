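"""Readers and writers for the plain-text genomics formats the pipeline uses.

FASTA goes through Biopython; BED/bedGraph/TSV through pandas; fixedStep
wiggle and MEME-minimal motif files are simple line formats handled here.
Every writer has a matching reader and round-trips to an equal in-memory
object (covered by tests).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]


# ---- FASTA ------------------------------------------------------------


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---- BED / intervals --------------------------------------------------


def write_bed(path: str | Path, df: pd.DataFrame) -> None:
    cols = [c for c in BED6_COLS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=BED6_COLS[:3])
    df.columns = BED6_COLS[: df.shape[1]]
    return df


# ---- bedGraph signal tracks -------------------------------------------


def write_bedgraph(path: str | Path, values: dict[str, np.ndarray]) -> None:
    """Run-length encode a per-base vector per chromosome."""
    with open(path, "w") as fh:
        for chrom in sorted(values):
            v = np.asarray(values[chrom], dtype=float)
            if v.size == 0:
                continue
            breaks = np.flatnonzero(np.diff(v) != 0) + 1
            starts = np.concatenate([[0], breaks])
            ends = np.concatenate([breaks, [v.size]])
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:g}\n")


def read_bedgraph(path: str | Path, chrom_sizes: dict[str, int]) -> dict[str, np.ndarray]:
    out = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"])
    for chrom, sub in df.groupby("chrom"):
        v = out[chrom]
        for s, e, x in zip(sub["start"], sub["end"], sub["value"]):
            v[s:e] = x
    return out


# ---- fixedStep wiggle (conservation scores) ---------------------------


def write_wig(path: str | Path, values: dict[str, np.ndarray]) -> None:
    """fixedStep step=1; NaN bases break the track into blocks (missing)."""
    with open(path, "w") as fh:
        for chrom in sorted(values):
            v = np.asarray(values[chrom], dtype=float)
            ok = ~np.isnan(v)
            if not ok.any():
                continue
            idx = np.flatnonzero(ok)
            block_starts = idx[np.concatenate([[True], np.diff(idx) != 1])]
            block_ends = idx[np.concatenate([np.diff(idx) != 1, [True]])]
            for bs, be in zip(block_starts, block_ends):
                fh.write(f"fixedStep chrom={chrom} start={bs + 1} step=1\n")
                fh.write("\n".join(f"{x:.6g}" for x in v[bs : be + 1]) + "\n")


def read_wig(path: str | Path, chrom_sizes: dict[str, int]) -> dict[str, np.ndarray]:
    out = {c: np.full(n, np.nan) for c, n in chrom_sizes.items()}
    chrom, pos, step = None, 0, 1
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                pos = int(fields["start"]) - 1  # wiggle is 1-based
                step = int(fields.get("step", 1))
            else:
                out[chrom][pos] = float(line)
                pos += step
    return out


# ---- MEME minimal motif format ----------------------------------------


def write_meme(path: str | Path, pwms) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write("A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*bg))
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.tf_id}\n")
            fh.write(
                f"letter-probability matrix: alphabet= ACGT w= {pwm.width} nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" " + " ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def read_meme(path: str | Path):
    from .motifs import PWM

    background = np.full(4, 0.25)
    pwms = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            vals = lines[i + 1].split()
            background = np.array([float(vals[j]) for j in (1, 3, 5, 7)])
            i += 2
        elif line.startswith("MOTIF"):
            tf_id = line.split()[1]
            i += 1
            while not lines[i].strip().startswith("letter-probability"):
                i += 1
            w = int(lines[i].split("w=")[1].split()[0])
            rows = []
            for j in range(w):
                rows.append([float(x) for x in lines[i + 1 + j].split()])
            pwms.append(PWM(tf_id=tf_id, matrix=np.array(rows), background=background.copy()))
            i += 1 + w
        else:
            i += 1
    return pwms


# ---- tables -----------------------------------------------------------


def write_counts(path: str | Path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
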
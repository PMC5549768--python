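"""Readers and writers for the plain-text formats used by the pipeline.

BED and bedGraph are 0-based half-open; narrowPeak follows the ENCODE
column layout (summit = start + 10th column offset, qValue column is
-log10).  Dense Hi-C matrices are TSV with a bin-start coordinate in the
first column and matching column headers.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .atac import FragmentSet, Summit
from .fourc import RegionSet, RestrictionFragmentMap
from .tads import ContactMatrix, TADSet

BED3 = ["chrom", "start", "end"]


def read_fasta_sequence(path: str, chrom: str | None = None) -> tuple[str, str]:
    """Return (chrom_name, sequence) for one record of a FASTA file."""
    fa = Fasta(path, as_raw=True, sequence_always_upper=True)
    keys = list(fa.keys())
    name = chrom if chrom is not None else keys[0]
    if name not in keys:
        raise KeyError(f"{name!r} not in {path} (records: {keys})")
    return name, str(fa[name][:])


def read_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns=dict(enumerate(BED3 + ["name", "score", "strand"])))
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_bed(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def write_fragments_bed(fs: FragmentSet, path: str) -> None:
    pd.DataFrame(
        {"chrom": fs.chrom, "start": fs.starts, "end": fs.ends, "name": fs.sample_id}
    ).to_csv(path, sep="\t", header=False, index=False)


def read_fragments_bed(
    path: str, sample_id: str, chrom: str | None = None, condition: str = ""
) -> FragmentSet:
    df = read_bed(path)
    if chrom is None:
        chrom = str(df["chrom"].iloc[0])
    df = df[df["chrom"] == chrom]
    return FragmentSet(
        sample_id=sample_id,
        chrom=chrom,
        starts=df["start"].to_numpy(),
        ends=df["end"].to_numpy(),
        condition=condition,
    )


def read_regions_bed(path: str) -> RegionSet:
    """Regions from a BED file with labels in the name column."""
    df = read_bed(path)
    if "name" not in df.columns:
        raise ValueError(f"{path}: regions BED needs a name column")
    return RegionSet.from_pairs(
        [(str(r["name"]), int(r["start"]), int(r["end"])) for _, r in df.iterrows()]
    )


def write_fragmap_bed(fragmap: RestrictionFragmentMap, path: str) -> None:
    pd.DataFrame(
        {"chrom": fragmap.chrom, "start": fragmap.starts, "end": fragmap.ends}
    ).to_csv(path, sep="\t", header=False, index=False)


def write_fragment_counts(
    fragmap: RestrictionFragmentMap, counts: np.ndarray, path: str
) -> None:
    pd.DataFrame(
        {
            "chrom": fragmap.chrom,
            "start": fragmap.starts,
            "end": fragmap.ends,
            "count": counts,
        }
    ).to_csv(path, sep="\t", index=False)


def read_fragment_counts(path: str) -> tuple[RestrictionFragmentMap, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    fragmap = RestrictionFragmentMap(
        chrom=str(df["chrom"].iloc[0]),
        starts=df["start"].to_numpy(np.int64),
        ends=df["end"].to_numpy(np.int64),
        enzyme_motif="GATC",
        cut_offset=0,
    )
    return fragmap, df["count"].to_numpy()


def write_bedgraph(
    chrom: str, starts: np.ndarray, ends: np.ndarray, values: np.ndarray, path: str
) -> None:
    pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "value": values}).to_csv(
        path, sep="\t", header=False, index=False
    )


def write_matrix_tsv(cm: ContactMatrix, path: str) -> None:
    starts = cm.offset + np.arange(cm.n_bins) * cm.bin_size
    df = pd.DataFrame(cm.matrix, index=starts, columns=starts)
    df.index.name = f"{cm.chrom}:{cm.bin_size}"
    df.to_csv(path, sep="\t")


def read_matrix_tsv(path: str) -> ContactMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    chrom, bin_size = str(df.index.name).rsplit(":", 1)
    starts = df.index.to_numpy(np.int64)
    return ContactMatrix(
        chrom=chrom,
        bin_size=int(bin_size),
        matrix=df.to_numpy(dtype=float),
        offset=int(starts[0]),
    )


def read_narrowpeak_summits(path: str, sample_id: str = "") -> list[Summit]:
    """Summits from a narrowPeak file (summit = start + peak column).

    The qValue column is -log10; converted back to a plain q-value.
    """
    cols = [
        "chrom", "start", "end", "name", "score",
        "strand", "signal", "pValue", "qValue", "peak",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    summits = []
    for _, row in df.iterrows():
        if int(row["peak"]) < 0:
            raise ValueError(f"{path}: narrowPeak record without summit offset")
        summits.append(
            Summit(
                position=int(row["start"]) + int(row["peak"]),
                q_value=float(min(10.0 ** (-float(row["qValue"])), 1.0)),
                sample_id=sample_id or str(row["name"]),
            )
        )
    return summits


def write_tads_tsv(tads: TADSet, chrom: str, path: str) -> None:
    pd.DataFrame(
        [(label, chrom, s, e) for label, s, e in tads.tads],
        columns=["label", "chrom", "start", "end"],
    ).to_csv(path, sep="\t", index=False)


def read_tads_tsv(path: str) -> tuple[TADSet, str]:
    df = pd.read_csv(path, sep="\t")
    tads = TADSet([(str(r["label"]), int(r["start"]), int(r["end"])) for _, r in df.iterrows()])
    return tads, str(df["chrom"].iloc[0])
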
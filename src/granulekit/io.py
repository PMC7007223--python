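"""Readers and writers for the formats shared across pipeline stages.

Images travel as multi-page TIFF (one page per channel), tabular results as
TSV, FRAP traces as CSV with ``time_s,intensity,background`` columns,
toeprints as BED6, gene models as BED12 (thick region = CDS, one block) and
gene sets as one-id-per-line text with ``#`` provenance headers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .frap import FrapTrace
from .iclip import GeneModel, GeneSet


def write_image(path, image: np.ndarray, pixel_size: float | None = None) -> None:
    """Write a (channels, y, x) image as a multi-page float32 TIFF.

    The pixel size (µm) is stored in the TIFF resolution tags so a round-trip
    through :func:`read_image` preserves it.
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim == 2:
        image = image[None]
    description = json.dumps({"axes": "CYX", "pixel_size_um": pixel_size})
    tifffile.imwrite(path, image, description=description)


def read_image(
    path, pixel_size: float | None = None, require_pixel_size: bool = False
) -> tuple[np.ndarray, dict]:
    """Read a multi-page TIFF into a (channels, y, x) array plus metadata.

    The pixel size comes from the file's description metadata when present,
    else from the ``pixel_size`` argument.  When a µm-dependent downstream
    step needs it (``require_pixel_size``) and neither source provides one,
    an error naming the ``--pixel-size`` flag is raised.
    """
    with tifffile.TiffFile(path) as tf:
        image = tf.asarray()
        px = pixel_size
        if px is None:
            desc = tf.pages[0].tags.get("ImageDescription")
            if desc is not None:
                try:
                    px = json.loads(desc.value).get("pixel_size_um")
                except (json.JSONDecodeError, AttributeError):
                    px = None
    if image.ndim == 2:
        image = image[None]
    if px is None and require_pixel_size:
        raise ValueError(
            "no pixel size in TIFF metadata; pass pixel_size (CLI: --pixel-size)"
        )
    return np.asarray(image, dtype=float), {"pixel_size": px, "n_channels": image.shape[0]}


def write_table(path, table: pd.DataFrame) -> None:
    """Write a result table as TSV, keeping the index when it is named."""
    table.to_csv(path, sep="\t", index=table.index.name is not None)


def read_table(path, index_col: str | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_trace(path, trace: FrapTrace) -> None:
    pd.DataFrame(
        {"time_s": trace.times, "intensity": trace.intensity, "background": trace.background}
    ).to_csv(path, index=False)


def read_trace(path, bleach_index: int) -> FrapTrace:
    df = pd.read_csv(path)
    return FrapTrace(
        times=df["time_s"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        background=df["background"].to_numpy(),
        bleach_index=bleach_index,
    )


def write_bed6(path, intervals: pd.DataFrame) -> None:
    intervals[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed6(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )


def write_gene_models_bed12(path, models: list[GeneModel]) -> None:
    """Gene models as single-block BED12; thickStart/thickEnd mark the CDS."""
    rows = []
    for g in models:
        if g.strand == "+":
            thick = (g.start + g.len_utr5, g.start + g.len_utr5 + g.len_cds)
        else:
            thick = (g.start + g.len_utr3, g.start + g.len_utr3 + g.len_cds)
        rows.append(
            (
                g.chrom, g.start, g.end, g.gene_id, 0, g.strand,
                thick[0], thick[1], "0,0,0", 1, g.length, 0,
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_gene_models_bed12(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", header=None)
    models = []
    for _, r in df.iterrows():
        start, end, strand = int(r[1]), int(r[2]), str(r[5])
        t0, t1 = int(r[6]), int(r[7])
        if strand == "+":
            l5, l3 = t0 - start, end - t1
        else:
            l5, l3 = end - t1, t0 - start
        models.append(
            GeneModel(
                gene_id=str(r[3]), chrom=str(r[0]), start=start, end=end,
                strand=strand, len_utr5=l5, len_cds=t1 - t0, len_utr3=l3,
            )
        )
    return models


def write_gene_set(path, gene_set: GeneSet) -> None:
    """One gene id per line, preceded by ``#``-prefixed provenance lines."""
    with open(path, "w") as fh:
        for key, val in gene_set.provenance.items():
            fh.write(f"# {key}: {val}\n")
        fh.write(f"# n_members: {len(gene_set)}\n")
        for gid in gene_set.members:
            fh.write(f"{gid}\n")


def read_gene_set(path) -> GeneSet:
    provenance: dict = {}
    members: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition(":")
                provenance[key.strip()] = val.strip()
            elif line:
                members.append(line)
    provenance.pop("n_members", None)
    return GeneSet(tuple(members), provenance=provenance)


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
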
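"""File I/O: TIFF/PNG micrographs, CSV manifests, FASTA and Newick."""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .align import Alignment, SequenceRecord
from .containers import Micrograph, MicrographMeta, ZStack

__all__ = [
    "micrograph_filename", "write_micrographs", "read_micrograph",
    "read_manifest", "write_zstack", "read_zstack",
    "write_fasta", "read_fasta", "write_alignment_fasta",
]

MANIFEST_COLUMNS = ["path", "species", "aef_fraction", "time_h", "replicate"]


def micrograph_filename(meta: MicrographMeta) -> str:
    aef = f"{meta.aef_fraction:g}".replace(".", "p")
    return f"{meta.species}_{aef}_{meta.time_h:g}h_{meta.replicate_id}.tif"


def write_micrographs(images: list[Micrograph], outdir) -> pd.DataFrame:
    """Write single-page TIFFs plus a manifest CSV; returns the manifest."""
    os.makedirs(outdir, exist_ok=True)
    rows = []
    for img in images:
        name = micrograph_filename(img.meta)
        tifffile.imwrite(os.path.join(outdir, name), img.pixels)
        rows.append({
            "path": name,
            "species": img.meta.species,
            "aef_fraction": img.meta.aef_fraction,
            "time_h": img.meta.time_h,
            "replicate": img.meta.replicate_id,
        })
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(os.path.join(outdir, "manifest.csv"), index=False,
                    float_format="%.10g")
    return manifest


def read_manifest(path) -> pd.DataFrame:
    manifest = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return manifest


def read_micrograph(path, meta: MicrographMeta | None = None) -> Micrograph:
    if str(path).lower().endswith((".tif", ".tiff")):
        px = tifffile.imread(path)
    else:
        from imageio.v3 import imread
        px = imread(path)
    bit_depth = 8 if px.dtype == np.uint8 else 16
    return Micrograph(pixels=px, bit_depth=bit_depth,
                      meta=meta or MicrographMeta())


def write_zstack(zs: ZStack, path) -> None:
    tifffile.imwrite(path, zs.slices)  # multi-page TIFF


def read_zstack(path, z_step: float = 1.0) -> ZStack:
    data = tifffile.imread(path)
    bit_depth = 8 if data.dtype == np.uint8 else 16
    return ZStack(slices=data, z_step=z_step, bit_depth=bit_depth)


def write_fasta(records: list[SequenceRecord], path) -> None:
    bio = [_BioRecord(Seq(r.residues), id=r.id, description=r.species)
           for r in records]
    SeqIO.write(bio, path, "fasta")


def read_fasta(path) -> list[SequenceRecord]:
    out = []
    for rec in SeqIO.parse(path, "fasta"):
        desc = rec.description.split(maxsplit=1)
        species = desc[1] if len(desc) > 1 else rec.id
        out.append(SequenceRecord(id=rec.id, species=species,
                                  residues=str(rec.seq).upper()))
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_alignment_fasta(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(aln.ids, aln.rows):
            fh.write(f">{rid}\n{row}\n")
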
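"""File-format helpers: TIFF stacks, FASTA, run manifests."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cyst3d import ImageStack

__all__ = ["read_stack", "write_stack", "write_fasta", "read_fasta", "write_manifest"]


def read_stack(
    path, pixel_size_um: Optional[float] = None, slice_spacing_um: float = 150.0
) -> ImageStack:
    """Read a multi-page TIFF, or a directory of ordered per-slice images,
    as an ImageStack."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff", ".png"))
        if not files:
            raise FileNotFoundError(f"no slice images found in {path}")
        slices = np.stack([tifffile.imread(f) if f.suffix.lower() != ".png"
                           else _read_png(f) for f in files])
    else:
        slices = tifffile.imread(path)
        if slices.ndim == 2:
            slices = slices[None]
    return ImageStack(slices=np.asarray(slices, dtype=float),
                      pixel_size_um=pixel_size_um, slice_spacing_um=slice_spacing_um)


def _read_png(path):
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 3:  # collapse RGB to grayscale
        img = img[..., :3].mean(axis=-1)
    return img


def write_stack(stack: ImageStack, path) -> None:
    """Write an ImageStack as a float32 multi-page TIFF."""
    tifffile.imwrite(str(path), stack.slices.astype(np.float32))


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_manifest(out_dir, config: dict, seed: Optional[int] = None) -> Path:
    """Write a reproducibility manifest (package version, config hash, seed)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "cystkit_version": __version__,
        "seed": seed,
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return path
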
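"""Readers and writers for the pipeline's plain-text artifact formats.

Everything is CSV/JSON/plain text plus PNG images: images load from a
directory (or an ``image_id,path`` manifest CSV), descriptions from CSV
(``image_id,description``) or JSON (``{image_id: [descriptions...]}``),
embeddings from the word2vec-style text format (word followed by d floats
per line, optional ``count dim`` header), and depth/response tables from
headed CSVs.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .semantic import DescriptionCorpus, EmbeddingTable
from .synthetic import SyntheticStudy
from .visual import SceneImage

IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")


# ---------------------------------------------------------------- images

def read_image(path: str | Path, image_id: str | None = None) -> SceneImage:
    path = Path(path)
    px = np.asarray(iio.imread(path))
    if px.ndim == 2:  # grayscale file: replicate channels
        px = np.stack([px] * 3, axis=-1)
    if px.shape[-1] == 4:  # drop alpha
        px = px[..., :3]
    return SceneImage(image_id=image_id or path.stem, pixels=px.astype(np.uint8))


def read_images(source: str | Path) -> list[SceneImage]:
    """Load a directory of PNG/JPEG files or an ``image_id,path`` manifest CSV."""
    source = Path(source)
    if source.is_dir():
        paths = sorted(
            p for p in source.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES
        )
        if not paths:
            raise FileNotFoundError(f"no images found in {source}")
        return [read_image(p) for p in paths]
    manifest = pd.read_csv(source)
    return [
        read_image(Path(source).parent / row["path"], image_id=str(row["image_id"]))
        for _, row in manifest.iterrows()
    ]


def write_image(img: SceneImage, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    path = directory / f"{img.image_id}.png"
    iio.imwrite(path, img.pixels)
    return path


# ----------------------------------------------------------- descriptions

def read_descriptions(path: str | Path) -> list[DescriptionCorpus]:
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return [
            DescriptionCorpus(image_id=str(k), descriptions=tuple(v))
            for k, v in sorted(data.items())
        ]
    df = pd.read_csv(path, dtype=str)
    return [
        DescriptionCorpus(image_id=str(iid), descriptions=tuple(grp["description"]))
        for iid, grp in df.groupby("image_id", sort=True)
    ]


def write_descriptions(corpora: list[DescriptionCorpus], path: str | Path) -> None:
    rows = [
        {"image_id": c.image_id, "description": d}
        for c in corpora
        for d in c.descriptions
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ------------------------------------------------------------- embeddings

def read_embeddings(path: str | Path) -> EmbeddingTable:
    """Word-vector text format: ``word v1 v2 ... vd`` per line.

    A leading ``count dim`` header line (two integer fields) is accepted
    and skipped.
    """
    vectors: dict[str, np.ndarray] = {}
    with open(path) as fh:
        first = fh.readline().split()
        if len(first) != 2 or not all(tok.lstrip("-").isdigit() for tok in first):
            if first:
                vectors[first[0]] = np.array(first[1:], dtype=float)
        for line in fh:
            parts = line.split()
            if parts:
                vectors[parts[0]] = np.array(parts[1:], dtype=float)
    return EmbeddingTable(vectors)


def write_embeddings(emb: EmbeddingTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(emb)} {emb.dim}\n")
        for word in sorted(emb.vocabulary):
            vec = " ".join(f"{x:.8g}" for x in emb.vector(word))
            fh.write(f"{word} {vec}\n")


# ----------------------------------------------------------------- tables

def read_table(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def read_depth(path: str | Path) -> pd.DataFrame:
    return read_table(path, ("image_id", "depth"))


def read_responses(path: str | Path) -> pd.DataFrame:
    return read_table(path, ("participant_id", "image_id", "response"))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


# ------------------------------------------------------------------ study

def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write a synthetic study to disk in the pipeline's input formats.

    Produces ``images/``, ``descriptions.csv``, ``embeddings.txt``,
    ``depth.csv``, ``responses.csv`` and ``truth.json`` (the hidden
    generative parameters, for tests only).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if study.images is not None:
        for img in study.images:
            write_image(img, outdir / "images")
        paths["images"] = outdir / "images"
    if study.corpora is not None:
        paths["descriptions"] = outdir / "descriptions.csv"
        write_descriptions(list(study.corpora), paths["descriptions"])
    if study.embeddings is not None:
        paths["embeddings"] = outdir / "embeddings.txt"
        write_embeddings(study.embeddings, paths["embeddings"])
    paths["depth"] = outdir / "depth.csv"
    write_table(study.depth_table(), paths["depth"])
    paths["responses"] = outdir / "responses.csv"
    write_table(study.responses, paths["responses"])
    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(json.dumps(study.truth(), indent=2))
    return paths
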
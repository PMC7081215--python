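"""Readers and writers for the pipeline's plain-text formats.

All files are diffable text.  Summary statistics and posteriors are
TSV with a header; LD matrices are whitespace-delimited with a
variant-id header row; annotations are BED (0-based half-open);
diameters are CSV with a JSON sidecar for depot metadata.  Every
writer prepends a ``#`` comment stating coordinate convention and
units so a file is self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .finemap import PosteriorSet
from .types import AnnotationTrack, DiameterSample, LDMatrix, SummaryStats

_SUMMARY_COLUMNS = ["variant_id", "pos", "beta", "se", "z", "n"]


def write_summary_stats(stats: SummaryStats, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "variant_id": stats.variant_ids,
            "pos": stats.positions,
            "beta": stats.beta,
            "se": stats.se,
            "z": stats.z,
            "n": stats.n,
        }
    )
    with open(path, "w") as fh:
        fh.write("# per-variant marginal association; pos in bp (1 locus); z = beta/se\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_summary_stats(path: str | Path) -> SummaryStats:
    """Header-driven TSV reader with per-line validation errors."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    offset = _header_line(path)  # 1-based line number of the header row
    dup = df["variant_id"].duplicated()
    if dup.any():
        i = int(np.argmax(dup.values))
        raise ValueError(
            f"{path}:{offset + 1 + i}: duplicate variant id {df['variant_id'].iloc[i]!r}"
        )
    numeric = {}
    for col in ("pos", "beta", "se", "z", "n"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            i = int(np.argmax(vals.isna().values))
            raise ValueError(
                f"{path}:{offset + 1 + i}: non-numeric value {df[col].iloc[i]!r} in column {col!r}"
            )
        numeric[col] = vals.to_numpy()
    if (numeric["se"] <= 0).any():
        i = int(np.argmax(numeric["se"] <= 0))
        raise ValueError(
            f"{path}:{offset + 1 + i}: non-positive se for variant {df['variant_id'].iloc[i]!r}"
        )
    return SummaryStats(
        variant_ids=df["variant_id"].tolist(),
        positions=numeric["pos"].astype(np.int64),
        beta=numeric["beta"],
        se=numeric["se"],
        z=numeric["z"],
        n=int(numeric["n"][0]),
    )


def _header_line(path: Path) -> int:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("#"):
                return lineno
    raise ValueError(f"{path}: no header row found")


def write_ld(ld: LDMatrix, path: str | Path, signed: bool = False) -> None:
    """Square matrix with a variant-id header row; r^2 or signed r."""
    path = Path(path)
    mat = ld.signed_r if signed else ld.values
    if mat is None:
        raise ValueError("signed-r requested but not present in this LDMatrix")
    with open(path, "w") as fh:
        fh.write(f"# square {'signed r' if signed else 'r^2'} matrix; header row = variant ids\n")
        fh.write("\t".join(ld.variant_ids) + "\n")
        np.savetxt(fh, mat, fmt="%.10g", delimiter="\t")


def read_ld(path: str | Path) -> LDMatrix:
    """Reads an r^2 or signed-r matrix; the header comment (or any
    negative entry) marks the signed case, from which r^2 is derived."""
    path = Path(path)
    signed_header = False
    with open(path) as fh:
        lines = []
        for ln in fh:
            if ln.startswith("#"):
                signed_header = signed_header or "signed" in ln
            else:
                lines.append(ln)
    if not lines:
        raise ValueError(f"{path}: empty LD file")
    ids = lines[0].split()
    mat = np.loadtxt(lines[1:], ndmin=2)
    if mat.shape != (len(ids), len(ids)):
        raise ValueError(f"{path}: matrix shape {mat.shape} does not match {len(ids)} ids")
    if signed_header or mat.min() < 0:
        return LDMatrix(values=mat**2, variant_ids=ids, signed_r=mat)
    return LDMatrix(values=mat, variant_ids=ids)


def write_bed(track: AnnotationTrack, path: str | Path, chrom: str = "locus") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# BED: 0-based half-open bp intervals on the simulated locus\n")
        for s, e in track.intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")


def read_bed(
    path: str | Path,
    window: tuple[int, int] | None = None,
    merge: bool = False,
    label: str = "",
) -> AnnotationTrack:
    """3+-column BED reader: clip to window, sort, optionally merge."""
    import warnings

    path = Path(path)
    intervals: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 tab-separated columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            if window is not None:
                w0, w1 = window
                if end <= w0 or start >= w1:
                    warnings.warn(f"{path}:{lineno}: interval outside window, dropped")
                    continue
                start, end = max(start, w0), min(end, w1)
            intervals.append((start, end))
    track = AnnotationTrack(intervals=intervals, label=label or path.stem)
    if merge:
        merged: list[tuple[int, int]] = []
        for s, e in track.intervals:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        track = AnnotationTrack(intervals=merged, label=track.label)
    return track


def write_posteriors(post: PosteriorSet, path: str | Path, top_k: int = 10) -> None:
    """TSV of per-variant PIPs plus a JSON of top configurations."""
    path = Path(path)
    df = pd.DataFrame(
        {"variant_id": post.variant_ids, "pos": post.positions, "pip": post.pip}
    )
    with open(path, "w") as fh:
        fh.write("# fine-mapping posterior inclusion probabilities; pos in bp\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    top = [
        {"config": [post.variant_ids[i] for i in c], "posterior": w}
        for c, w in post.top_configurations(top_k)
    ]
    Path(str(path) + ".configs.json").write_text(
        json.dumps({"max_k": post.max_k, "top_configurations": top}, indent=1)
    )


def read_posteriors(path: str | Path) -> tuple[list[str], np.ndarray, np.ndarray]:
    """PIP TSV -> (variant_ids, positions, pip); config table not round-tripped."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("variant_id", "pos", "pip"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return (
        df["variant_id"].astype(str).tolist(),
        df["pos"].to_numpy(np.int64),
        df["pip"].to_numpy(float),
    )


def write_diameters(sample: DiameterSample, path: str | Path) -> None:
    """CSV `cell_id,diameter_um` plus a JSON sidecar with depot metadata."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "cell_id": [f"cell{i:05d}" for i in range(sample.n_cells)],
            "diameter_um": sample.diameters_um,
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")
    sidecar = {
        "depot": sample.depot,
        "animal_id": sample.animal_id,
        "depot_mass_g": sample.depot_mass_g,
        "units": {"diameter": "um", "mass": "g"},
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=1))


def read_diameters(path: str | Path) -> DiameterSample:
    path = Path(path)
    df = pd.read_csv(path)
    if "diameter_um" not in df.columns:
        raise ValueError(f"{path}: missing column 'diameter_um'")
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return DiameterSample(
        diameters_um=df["diameter_um"].to_numpy(float),
        depot=meta.get("depot", ""),
        animal_id=meta.get("animal_id", ""),
        depot_mass_g=float(meta.get("depot_mass_g", "nan")),
    )
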
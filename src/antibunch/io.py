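"""Readers and writers for the on-disk interchange formats.

Everything is human-diffable CSV/JSON; TIFF is available for image
export.  A scan lives in one directory:

    scandir/
      config.json       scan geometry + emitters (+ seed)
      pl_map.csv        grid of detected photon counts
      histograms.csv    long format: row, col, slice, bin_0..bin_N

Every artifact writer drops a JSON sidecar (<name>.meta.json) carrying
a hash of the generating configuration and the seed, so outputs are
traceable and reruns comparable.  Integer fields round-trip exactly;
reals to full repr precision.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import LabeledHistogram
from .emitter import EmitterSpec
from .fitting import G2Map
from .histogram import CorrelationHistogram, HistogramFormat
from .reconstruct import GaussianFit, SRImage
from .simulate import ScanConfig, ScanDataset

__all__ = [
    "write_scan",
    "read_scan",
    "write_g2map",
    "read_g2map",
    "write_corpus",
    "read_corpus",
    "write_sr_image",
    "read_sr_image",
    "write_fits_json",
    "write_sidecar",
]


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def write_sidecar(path: Path, config: dict, seed: int | None, extra: dict | None = None) -> None:
    meta = {"config_hash": config_hash(config), "seed": seed}
    if extra:
        meta.update(extra)
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=2))


# ----------------------------------------------------------------- scans


def write_scan(scan: ScanDataset, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = {
        "scan": scan.config.to_dict(),
        "emitters": [e.to_dict() for e in scan.emitters],
    }
    (directory / "config.json").write_text(json.dumps(cfg, indent=2))

    rows, cols = scan.config.grid
    pd.DataFrame(scan.pl_map).to_csv(directory / "pl_map.csv", index=False)

    n_bins = scan.config.histogram_format.n_bins
    flat = scan.histograms.reshape(-1, n_bins)
    r, c, s = np.meshgrid(
        np.arange(rows),
        np.arange(cols),
        np.arange(scan.config.slices_per_pixel),
        indexing="ij",
    )
    df = pd.DataFrame(
        {"row": r.ravel(), "col": c.ravel(), "slice": s.ravel()}
        | {f"bin_{i}": flat[:, i] for i in range(n_bins)}
    )
    df.to_csv(directory / "histograms.csv", index=False)
    write_sidecar(directory / "scan", cfg, scan.config.seed)
    return directory


def read_scan(directory: str | Path) -> ScanDataset:
    directory = Path(directory)
    cfg = json.loads((directory / "config.json").read_text())
    config = ScanConfig.from_dict(cfg["scan"])
    emitters = [EmitterSpec.from_dict(d) for d in cfg["emitters"]]
    pl = pd.read_csv(directory / "pl_map.csv").to_numpy(dtype=float)
    df = pd.read_csv(directory / "histograms.csv")
    n_bins = config.histogram_format.n_bins
    bin_cols = [f"bin_{i}" for i in range(n_bins)]
    for col in ("row", "col", "slice", *bin_cols):
        if col not in df.columns:
            raise ValueError(f"histograms.csv is missing column {col!r}")
    counts = df[bin_cols].to_numpy()
    if np.any(counts < 0):
        bad = int(np.argwhere((counts < 0).any(axis=1))[0][0])
        raise ValueError(f"histograms.csv row {bad + 2}: negative count")
    rows, cols = config.grid
    hists = np.zeros((rows, cols, config.slices_per_pixel, n_bins), dtype=np.int64)
    hists[df["row"], df["col"], df["slice"]] = counts
    return ScanDataset(config=config, emitters=emitters, pl_map=pl, histograms=hists)


def export_pl_tiff(scan: ScanDataset, path: str | Path) -> None:
    """Optional TIFF export of the photoluminescence map."""
    import tifffile

    tifffile.imwrite(str(path), scan.pl_map.astype(np.float32))


# ----------------------------------------------------------------- g2 maps


def write_g2map(g2map: G2Map, path: str | Path, converged: np.ndarray | None = None) -> None:
    rows, cols = g2map.values.shape
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    unc = (
        g2map.uncertainties
        if g2map.uncertainties is not None
        else np.full_like(g2map.values, np.nan)
    )
    conv = converged if converged is not None else np.isfinite(unc)
    pd.DataFrame(
        {
            "row": r.ravel(),
            "col": c.ravel(),
            "g2_zero": g2map.values.ravel(),
            "uncertainty": unc.ravel(),
            "converged": conv.ravel().astype(bool),
        }
    ).to_csv(path, index=False)


def read_g2map(path: str | Path) -> G2Map:
    df = pd.read_csv(path)
    rows = int(df["row"].max()) + 1
    cols = int(df["col"].max()) + 1
    values = np.full((rows, cols), np.nan)
    unc = np.full((rows, cols), np.nan)
    values[df["row"], df["col"]] = df["g2_zero"]
    unc[df["row"], df["col"]] = df["uncertainty"]
    return G2Map(values=values, uncertainties=unc)


# ----------------------------------------------------------------- corpora


def write_corpus(items: Sequence[LabeledHistogram], path: str | Path) -> None:
    n_bins = items[0].histogram.format.n_bins
    rows = {
        "label": [it.label for it in items],
        "acquisition_time": [it.histogram.acquisition_time for it in items],
        "n_events": [it.histogram.n_events for it in items],
        "scenario_id": [it.scenario_id for it in items],
    }
    counts = np.stack([it.histogram.counts for it in items])
    rows |= {f"bin_{i}": counts[:, i] for i in range(n_bins)}
    pd.DataFrame(rows).to_csv(path, index=False)


def read_corpus(path: str | Path, fmt: HistogramFormat | None = None) -> list[LabeledHistogram]:
    df = pd.read_csv(path)
    bin_cols = [c for c in df.columns if c.startswith("bin_")]
    fmt = fmt or HistogramFormat(n_bins=len(bin_cols))
    counts = df[bin_cols].to_numpy()
    if np.any(counts < 0):
        bad = int(np.argwhere((counts < 0).any(axis=1))[0][0])
        raise ValueError(f"{path}: line {bad + 2} has a negative count")
    items = []
    for i in range(len(df)):
        h = CorrelationHistogram(
            counts=counts[i],
            format=fmt,
            acquisition_time=float(df["acquisition_time"].iloc[i]),
        )
        items.append(
            LabeledHistogram(
                histogram=h,
                label=float(df["label"].iloc[i]),
                scenario_id=int(df.get("scenario_id", pd.Series([0] * len(df))).iloc[i]),
            )
        )
    return items


# ----------------------------------------------------------------- images


def write_sr_image(image: SRImage, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), image.values.astype(np.float32))
    else:
        pd.DataFrame(image.values).to_csv(path, index=False)
    meta = {"pixel_pitch_nm": image.pixel_pitch, "n_clamped": image.n_clamped}
    write_sidecar(path, meta, None, extra=meta)


def read_sr_image(path: str | Path, pixel_pitch: float | None = None) -> SRImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        values = np.asarray(tifffile.imread(str(path)), dtype=float)
    else:
        values = pd.read_csv(path).to_numpy(dtype=float)
    if pixel_pitch is None:
        meta_path = Path(str(path) + ".meta.json")
        pixel_pitch = 1.0
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            pixel_pitch = float(meta.get("pixel_pitch_nm", 1.0))
    return SRImage(values=values, pixel_pitch=pixel_pitch)


def write_fits_json(fits: Sequence[GaussianFit], path: str | Path) -> None:
    out = [
        {
            "amplitude": f.amplitude,
            "center_nm": f.center,
            "sigma_nm": f.sigma,
            "offset": f.offset,
            "fwhm_nm": f.fwhm,
        }
        for f in fits
    ]
    Path(path).write_text(json.dumps(out, indent=2))
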
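"""Serialization: RGB agent-map TIFFs, YAML configs, JSONL logs, manifests.

Agent maps are written as RGB TIFFs with a fixed documented palette (one
color per cell class); the reader inverts the palette exactly and rejects
unknown colors.  The palette is this package's convention — any consistent
color coding carries the same information.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .params import BioParams, PhenotypeConfig, get_preset
from .world import AgentGrid, CellState

#: RGB palette for agent-map TIFF export.
PALETTE: dict[CellState, tuple[int, int, int]] = {
    CellState.VESSEL: (255, 0, 0),
    CellState.NORMAL: (255, 255, 255),
    CellState.TUMOR_NORMOXIC: (0, 128, 0),
    CellState.TUMOR_HYPOXIC: (0, 0, 255),
    CellState.TUMOR_NECROTIC: (0, 0, 0),
}


def write_agent_tiff(grid: AgentGrid, path: str | Path) -> None:
    rgb = np.zeros((*grid.dims, 3), dtype=np.uint8)
    for state, color in PALETTE.items():
        rgb[grid.states == int(state)] = color
    tifffile.imwrite(str(path), rgb, photometric="rgb")


def read_agent_tiff(path: str | Path, pixel_um: float = 20.0) -> AgentGrid:
    rgb = tifffile.imread(str(path))
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"{path}: expected an RGB agent map")
    states = np.full(rgb.shape[:2], 255, dtype=np.uint8)
    for state, color in PALETTE.items():
        states[(rgb == np.array(color, dtype=np.uint8)).all(axis=2)] = int(state)
    if (states == 255).any():
        bad = rgb[states == 255][0]
        raise ValueError(f"{path}: unknown palette color {tuple(int(v) for v in bad)}")
    return AgentGrid(states, pixel_um=pixel_um)


def write_float_tiff(values: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), np.asarray(values, dtype=np.float32))


# Configuration ---------------------------------------------------------------


def load_phenotype_yaml(path: str | Path) -> PhenotypeConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    cfg = PhenotypeConfig(**data)
    cfg.validate()
    return cfg


def dump_phenotype_yaml(config: PhenotypeConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def load_preset_or_yaml(name_or_path: str, seed: int | None = None) -> PhenotypeConfig:
    """Resolve a phenotype by preset letter (A–F) or YAML file path."""
    p = Path(name_or_path)
    if p.suffix in (".yaml", ".yml") or p.exists():
        cfg = load_phenotype_yaml(p)
        return cfg.with_seed(seed) if seed is not None else cfg
    return get_preset(name_or_path, seed=seed)


def preset_yaml_path(name: str) -> Path:
    """Path to a shipped preset YAML (useful as a template)."""
    res = importlib.resources.files("tumorpet") / "presets" / f"{name.upper()}.yaml"
    return Path(str(res))


# Logs and manifests ----------------------------------------------------------


def write_jsonl(records: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def read_jsonl(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    config: PhenotypeConfig,
    bio: BioParams,
    seed: int | None,
    extra: dict | None = None,
) -> Path:
    """Record the resolved configuration and checksums of every output file."""
    out_dir = Path(out_dir)
    files = sorted(
        p for p in out_dir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": asdict(config),
        "bio": asdict(bio),
        "seed": seed,
        "extra": extra or {},
        "files": {str(p.relative_to(out_dir)): _sha256(p) for p in files},
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path


# Test fixtures ---------------------------------------------------------------


def make_fixture(name: str):
    """Deterministic small worlds/images with known ground truth.

    Registry: "disc" (recon-scale pSUV disc of known area on background 1),
    "two-phase" (half/half intensity image), "uniform-phantom-2.37" (the
    noise-calibration reference), "mini-A" (300×300 phenotype-A grid,
    seed 7, vessels placed, tumor seeded).
    """
    from .pet import PHANTOM_PSUV, AcquisitionSettings, PSUVImage
    from .world import place_vessels, seed_tumor

    acq = AcquisitionSettings()
    n = acq.recon_pixels
    if name == "uniform-phantom-2.37":
        return PSUVImage(np.full((n, n), PHANTOM_PSUV), pixel_mm=acq.recon_pixel_mm)
    if name == "disc":
        yy, xx = np.mgrid[:n, :n]
        r_px = 10.0 / 2.0 / acq.recon_pixel_mm  # 10 mm diameter disc
        disc = (yy - n / 2 + 0.5) ** 2 + (xx - n / 2 + 0.5) ** 2 <= r_px**2
        values = np.where(disc, 8.0, 1.0)
        return PSUVImage(values, pixel_mm=acq.recon_pixel_mm)
    if name == "two-phase":
        values = np.ones((n, n))
        values[:, n // 2 :] = 2.0
        return PSUVImage(values, pixel_mm=acq.recon_pixel_mm)
    if name == "mini-A":
        cfg = get_preset("A", seed=7)
        grid = place_vessels(cfg, BioParams(), dims=(300, 300))
        return seed_tumor(grid)
    raise KeyError(f"unknown fixture {name!r}")
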
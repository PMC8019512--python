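"""Readers and writers: block CSVs, model bundles, profiles and reports.

Conventions: comma-separated UTF-8 CSV with a mandatory header row and '.'
decimals; matrices are samples x variables with the sample id in the first
column; floats are written with 17 significant digits so every round trip is
exact to full double precision.  Variable indices in user-facing files are
1-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    ComponentSpec,
    DecomposedModel,
    MultiblockDataset,
    build_ssd_table,
)
from .importance import PROFILE_KINDS, VIOPProfiles, connectivity_degree, select_variables
from .simulate import GaussianProfile, PulseProfile, SyntheticDesign

__all__ = [
    "read_blocks",
    "write_blocks",
    "save_model",
    "load_model",
    "write_profiles",
    "read_profiles",
    "write_explained_variation",
    "save_design",
    "load_design",
]

_FLOAT = "%.17g"


# ---------------------------------------------------------------------------
# Blocks


def read_blocks(paths, block_names=None) -> MultiblockDataset:
    """Read one CSV per block and align rows by sample id.

    The first column of each file holds sample ids; samples are reordered to
    match the first file.  Mismatched sample sets, missing values and
    non-numeric cells are reported with their location.
    """
    paths = [Path(p) for p in paths]
    if block_names is None:
        block_names = [p.stem for p in paths]
    frames = []
    for path, name in zip(paths, block_names):
        if not path.exists():
            raise FileNotFoundError(f"block file not found: {path}")
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        df.index = df.index.astype(str)
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.argmax()]
                raise ValueError(
                    f"non-numeric value in {path.name}, row {row!r}, column {col!r}"
                )
            df[col] = coerced
        if df.isna().any().any():
            col = df.columns[df.isna().any().argmax()]
            row = df.index[df[col].isna().argmax()]
            raise ValueError(
                f"missing value in {path.name}, row {row!r}, column {col!r}"
            )
        frames.append(df)
    ref_ids = list(frames[0].index)
    for path, df in zip(paths[1:], frames[1:]):
        if set(df.index) != set(ref_ids):
            raise ValueError(
                f"sample ids in {path.name} do not match the first block"
            )
    frames = [df.loc[ref_ids] for df in frames]
    return MultiblockDataset(
        blocks=[df.to_numpy(dtype=float) for df in frames],
        block_names=list(block_names),
        variable_names=[list(df.columns) for df in frames],
        sample_ids=ref_ids,
    )


def write_blocks(dataset: MultiblockDataset, out_dir) -> list[Path]:
    """Write one ``<block>.csv`` per block (first column = sample id)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for block, name, var_names in zip(
        dataset.blocks, dataset.block_names, dataset.variable_names
    ):
        df = pd.DataFrame(block, index=dataset.sample_ids, columns=var_names)
        df.index.name = "sample_id"
        path = out_dir / f"{name}.csv"
        df.to_csv(path, float_format=_FLOAT)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Model bundles


def save_model(
    model: DecomposedModel,
    out_dir,
    block_names: list[str] | None = None,
    provenance: dict | None = None,
) -> Path:
    """Serialize a model to a bundle directory.

    Layout: ``model.json`` (components, membership, block names and sizes,
    beta per block, provenance) + ``scores.csv`` + one
    ``loadings_<block>.csv`` per block with the member components as columns.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_blocks = 1 + max(d for c in model.components for d in c.member_blocks)
    if block_names is None:
        block_names = [f"D{i + 1}" for i in range(n_blocks)]
    block_sizes = {}
    for (cid, d), p in model.loadings.items():
        block_sizes[d] = p.shape[0]

    meta = {
        "format": "mbviop-model-bundle",
        "software_version": __version__,
        "block_names": list(block_names),
        "block_sizes": [block_sizes[d] for d in range(n_blocks)],
        "components": [
            {
                "component_id": c.component_id,
                "kind": c.kind,
                "member_blocks": sorted(c.member_blocks),
            }
            for c in model.components
        ],
        "beta": [connectivity_degree(model, d) for d in range(n_blocks)],
    }
    if provenance:
        meta["provenance"] = provenance
    (out_dir / "model.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    scores = pd.DataFrame(model.scores, columns=model.component_ids)
    scores.to_csv(out_dir / "scores.csv", index=False, float_format=_FLOAT)

    for d in range(n_blocks):
        member = [c.component_id for c in model.components if d in c.member_blocks]
        df = pd.DataFrame({cid: model.loadings[(cid, d)] for cid in member})
        df.to_csv(out_dir / f"loadings_{block_names[d]}.csv", index=False,
                  float_format=_FLOAT)
    return out_dir


def load_model(path) -> DecomposedModel:
    """Load a model bundle, validating membership consistency."""
    path = Path(path)
    meta_path = path / "model.json"
    if not meta_path.exists():
        raise ValueError(f"not a model bundle (no model.json): {path}")
    meta = json.loads(meta_path.read_text())
    if meta.get("format") != "mbviop-model-bundle":
        raise ValueError(f"unrecognized bundle format in {meta_path}")
    components = [
        ComponentSpec(c["component_id"], c["kind"], frozenset(c["member_blocks"]))
        for c in meta["components"]
    ]
    scores_df = pd.read_csv(path / "scores.csv", float_precision="round_trip")
    ids = [c.component_id for c in components]
    if list(scores_df.columns) != ids:
        raise ValueError("scores.csv columns do not match model.json components")
    loadings: dict[tuple[str, int], np.ndarray] = {}
    for d, name in enumerate(meta["block_names"]):
        lpath = path / f"loadings_{name}.csv"
        if not lpath.exists():
            raise ValueError(f"missing loadings file for block {name!r}")
        df = pd.read_csv(lpath, float_precision="round_trip")
        member = [c.component_id for c in components if d in c.member_blocks]
        if sorted(df.columns) != sorted(member):
            raise ValueError(
                f"loadings_{name}.csv columns do not match the membership "
                f"declared in model.json"
            )
        if len(df) != meta["block_sizes"][d]:
            raise ValueError(f"loadings_{name}.csv has the wrong number of rows")
        for cid in member:
            loadings[(cid, d)] = df[cid].to_numpy(dtype=float)
    model = DecomposedModel(
        components=components, scores=scores_df.to_numpy(dtype=float),
        loadings=loadings,
    )
    model.validate(n_blocks=len(meta["block_names"]), norm_tol=1e-6, center_tol=1e-6)
    return model


# ---------------------------------------------------------------------------
# Profiles and reports


def write_profiles(profiles: VIOPProfiles, out_dir,
                   thresholds: tuple[float, ...] = (1.0, 0.5)) -> Path:
    """Write per-block profile CSVs plus a JSON summary.

    Each ``profiles_<block>.csv`` has columns variable, unique, local,
    global, total; ``summary.json`` records beta per block, empty-profile
    flags and the 1-based selections at the given thresholds.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    selections: dict[str, dict] = {}
    for d, name in enumerate(profiles.block_names):
        df = profiles.to_frame(d)
        df.to_csv(out_dir / f"profiles_{name}.csv", index=False, float_format=_FLOAT)
        per_kind = {}
        for kind in PROFILE_KINDS:
            per_kind[kind] = {
                f"threshold_{thr:g}": []
                if profiles.is_empty(d, kind)
                else [int(k) + 1 for k in select_variables(profiles, d, kind, thr)]
                for thr in thresholds
            }
        selections[name] = per_kind
    summary = {
        "block_names": profiles.block_names,
        "beta": profiles.beta,
        "empty_profiles": sorted(
            [profiles.block_names[d], kind] for d, kind in profiles.empty
        ),
        "selections": selections,
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return out_dir


def read_profiles(path) -> VIOPProfiles:
    """Load profiles written by :func:`write_profiles`."""
    path = Path(path)
    summary = json.loads((path / "summary.json").read_text())
    block_names = summary["block_names"]
    values: dict[tuple[int, str], np.ndarray] = {}
    variable_names = []
    for d, name in enumerate(block_names):
        df = pd.read_csv(path / f"profiles_{name}.csv", float_precision="round_trip")
        variable_names.append([str(v) for v in df["variable"]])
        for kind in PROFILE_KINDS:
            values[(d, kind)] = df[kind].to_numpy(dtype=float)
    empty = {
        (block_names.index(bname), kind) for bname, kind in summary["empty_profiles"]
    }
    return VIOPProfiles(
        block_names=block_names,
        variable_names=variable_names,
        values=values,
        beta=[int(b) for b in summary["beta"]],
        empty=empty,
    )


def write_explained_variation(
    model: DecomposedModel, dataset: MultiblockDataset, path
) -> Path:
    """Long-format percent-explained table, 1 decimal place.

    Columns: block, component, kind, percent_explained; a TOTAL
    pseudo-component row closes each block.
    """
    table = build_ssd_table(model, dataset)
    rows = []
    for d, name in enumerate(dataset.block_names):
        for c in model.components:
            if d in c.member_blocks:
                pct = 100.0 * table.ssd[(c.component_id, d)] / table.ss_total[d]
                rows.append((name, c.component_id, c.kind, round(pct, 1)))
        rows.append(
            (name, "TOTAL", "", round(100.0 * table.ssd_cum[d] / table.ss_total[d], 1))
        )
    path = Path(path)
    pd.DataFrame(
        rows, columns=["block", "component", "kind", "percent_explained"]
    ).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Designs


def save_design(design: SyntheticDesign, path) -> Path:
    """Serialize a synthetic design to JSON."""
    def encode(prof):
        if isinstance(prof, GaussianProfile):
            return {"shape": "gaussian", "center": prof.center, "width": prof.width}
        return {"shape": "pulse", "start": prof.start, "end": prof.end}

    payload = {
        "n_samples": design.n_samples,
        "block_sizes": list(design.block_sizes),
        "block_names": list(design.block_names),
        "noise_level": design.noise_level,
        "seed": design.seed,
        "components": [
            {
                "component_id": c.component_id,
                "kind": c.kind,
                "member_blocks": sorted(c.member_blocks),
            }
            for c in design.components
        ],
        "profiles": [
            {"component_id": cid, "block": d, **encode(prof)}
            for (cid, d), prof in sorted(design.profiles.items())
        ],
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_design(path) -> SyntheticDesign:
    payload = json.loads(Path(path).read_text())
    components = [
        ComponentSpec(c["component_id"], c["kind"], frozenset(c["member_blocks"]))
        for c in payload["components"]
    ]
    profiles = {}
    for entry in payload["profiles"]:
        key = (entry["component_id"], int(entry["block"]))
        if entry["shape"] == "gaussian":
            profiles[key] = GaussianProfile(entry["center"], entry["width"])
        elif entry["shape"] == "pulse":
            profiles[key] = PulseProfile(entry["start"], entry["end"])
        else:
            raise ValueError(f"unknown profile shape {entry['shape']!r}")
    return SyntheticDesign(
        n_samples=payload["n_samples"],
        block_sizes=payload["block_sizes"],
        components=components,
        profiles=profiles,
        noise_level=payload["noise_level"],
        seed=payload["seed"],
        block_names=payload["block_names"],
    )
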
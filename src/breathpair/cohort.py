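"""The Cohort container: per-sample feature blocks keyed by (subject, visit).

A cohort holds one DataFrame per named block, all sharing an identical
(subject, visit) MultiIndex, plus a boolean availability mask of the same
shape (True = observed). Missing cells keep their underlying simulated value
in memory but are written as empty cells on disk.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError

_MANIFEST = "_cohort.yaml"


@dataclass
class Cohort:
    """Aligned multi-block data for one crossover cohort."""

    blocks: dict[str, pd.DataFrame]
    masks: dict[str, pd.DataFrame]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("cohort must contain at least one block")
        ref = next(iter(self.blocks.values())).index
        if ref.has_duplicates:
            raise ParseError("duplicated (subject, visit) keys in cohort index")
        for name, df in self.blocks.items():
            if not df.index.equals(ref):
                raise ValueError(f"block {name!r} sample index differs from the first block")
            if name not in self.masks:
                self.masks[name] = pd.DataFrame(
                    True, index=df.index, columns=df.columns
                )

    @property
    def samples(self) -> pd.MultiIndex:
        return next(iter(self.blocks.values())).index

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.samples.get_level_values("subject")))

    @property
    def visits(self) -> list[str]:
        return list(dict.fromkeys(self.samples.get_level_values("visit")))

    @property
    def block_names(self) -> list[str]:
        return list(self.blocks)

    def n_samples(self) -> int:
        return len(self.samples)

    def observed(self, block: str) -> pd.DataFrame:
        """Block values with unavailable cells replaced by NaN."""
        return self.blocks[block].where(self.masks[block])

    def feature_blocks(self) -> dict[str, str]:
        """Map feature name -> owning block (features assumed globally unique)."""
        out: dict[str, str] = {}
        for name, df in self.blocks.items():
            for col in df.columns:
                out[col] = name
        return out


def cohorts_equal(a: Cohort, b: Cohort, rtol: float = 0.0, atol: float = 0.0) -> bool:
    """Equality on keys, masks, and observed values (masked cells ignored)."""
    if list(a.blocks) != list(b.blocks):
        return False
    for name in a.blocks:
        da, db = a.blocks[name], b.blocks[name]
        if not da.index.equals(db.index) or list(da.columns) != list(db.columns):
            return False
        ma, mb = a.masks[name].to_numpy(), b.masks[name].to_numpy()
        if not np.array_equal(ma, mb):
            return False
        va, vb = da.to_numpy(), db.to_numpy()
        if rtol == 0.0 and atol == 0.0:
            if not np.array_equal(va[ma], vb[mb]):
                return False
        elif not np.allclose(va[ma], vb[mb], rtol=rtol, atol=atol):
            return False
    return True


# ---------------------------------------------------------------------------
# Delimited-text persistence: one CSV per block, `subject,visit,<features...>`
# ---------------------------------------------------------------------------


def write_cohort(cohort: Cohort, path) -> None:
    """Write one CSV per block plus a small manifest preserving block order."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in cohort.blocks.items():
        mask = cohort.masks[name].to_numpy()
        with open(out / f"{name}.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["subject", "visit", *df.columns])
            for i, (subject, visit) in enumerate(df.index):
                row = [subject, visit]
                for j, value in enumerate(df.iloc[i]):
                    row.append(repr(float(value)) if mask[i, j] else "")
                writer.writerow(row)
    manifest = {"blocks": list(cohort.blocks), "provenance": _yaml_safe(cohort.provenance)}
    with open(out / _MANIFEST, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)


def _yaml_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def read_cohort(path) -> Cohort:
    """Read a cohort directory written by :func:`write_cohort`.

    Also accepts a bare directory of ``*.csv`` block tables (no manifest), in
    which case blocks are loaded in sorted filename order.
    """
    src = Path(path)
    manifest_path = src / _MANIFEST
    provenance: dict = {"source": str(src)}
    if manifest_path.exists():
        with open(manifest_path) as fh:
            manifest = yaml.safe_load(fh) or {}
        names = manifest.get("blocks", [])
        provenance.update(manifest.get("provenance") or {})
    else:
        names = sorted(p.stem for p in src.glob("*.csv"))
    if not names:
        raise ParseError(f"no cohort block tables found under {src}")
    blocks: dict[str, pd.DataFrame] = {}
    masks: dict[str, pd.DataFrame] = {}
    for name in names:
        blocks[name], masks[name] = _read_block(src / f"{name}.csv")
    return Cohort(blocks=blocks, masks=masks, provenance=provenance)


def _read_block(path: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path.name}: empty file") from None
        if header[:2] != ["subject", "visit"]:
            raise ParseError(
                f"{path.name}: row 1: header must start with 'subject,visit'"
            )
        features = header[2:]
        if not features:
            raise ParseError(f"{path.name}: row 1: no feature columns")
        keys: list[tuple[str, str]] = []
        values: list[list[float]] = []
        observed: list[list[bool]] = []
        seen: set[tuple[str, str]] = set()
        for rownum, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise ParseError(
                    f"{path.name}: row {rownum}: expected {len(header)} fields, "
                    f"got {len(row)} (ragged row)"
                )
            key = (row[0], row[1])
            if key in seen:
                raise ParseError(
                    f"{path.name}: row {rownum}: duplicated (subject, visit) key {key}"
                )
            seen.add(key)
            keys.append(key)
            vals, obs = [], []
            for j, cell in enumerate(row[2:]):
                if cell == "":
                    vals.append(np.nan)
                    obs.append(False)
                else:
                    try:
                        vals.append(float(cell))
                    except ValueError:
                        raise ParseError(
                            f"{path.name}: row {rownum}: column "
                            f"{features[j]!r}: not a number: {cell!r}"
                        ) from None
                    obs.append(True)
            values.append(vals)
            observed.append(obs)
    index = pd.MultiIndex.from_tuples(keys, names=["subject", "visit"])
    df = pd.DataFrame(values, index=index, columns=features, dtype=float)
    mask = pd.DataFrame(observed, index=index, columns=features, dtype=bool)
    # unobserved cells carry no stored value; keep 0.0 placeholder under NaN-free mask
    df = df.where(mask, 0.0)
    return df, mask
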
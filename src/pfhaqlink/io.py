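"""File formats: response matrices, item parameters, crosswalk tables.

All artifacts are UTF-8 comma-separated text with a mandatory header
row; empty cells denote missing values.  Crosswalk and parameter files
carry a small metadata block as ``#``-prefixed comment lines.  Readers
and writers round-trip every file produced by this package bit-exactly.
"""

from __future__ import annotations

import csv
import io as _io
import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .diagnostics import FitReport
from .instruments import MISSING, HaqMethod
from .irt import ItemParams, ModelKind
from .linking import Crosswalk, HAQ_CATEGORY_IDS, PF10_ITEM_IDS

__all__ = [
    "write_pf10_csv",
    "read_pf10_csv",
    "write_haq_csv",
    "read_haq_csv",
    "write_item_params",
    "read_item_params",
    "write_crosswalk_csv",
    "read_crosswalk_csv",
    "load_published_crosswalk",
    "write_fit_report",
    "write_manifest",
]

FORMAT_VERSION = "pfhaqlink crosswalk v1"

PF10_COLUMNS = list(PF10_ITEM_IDS)
HAQ_ITEM_COLUMNS = [f"haq{i:02d}" for i in range(1, 21)]
AID_COLUMNS = [f"aid_{c}" for c in HAQ_CATEGORY_IDS]


# ---------------------------------------------------------------------------
# response matrices


def _write_matrix(path, columns: Sequence[str], matrix: np.ndarray) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(columns)
        for row in np.asarray(matrix):
            w.writerow(["" if v == MISSING else int(v) for v in row])


def _read_matrix(path, columns: Sequence[str]) -> np.ndarray:
    df = pd.read_csv(path, dtype="Int64")
    missing_cols = [c for c in columns if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing expected columns {missing_cols}")
    arr = df[list(columns)].to_numpy(dtype=object)
    out = np.full(arr.shape, MISSING, dtype=int)
    mask = ~pd.isna(arr)
    out[mask] = arr[mask].astype(int)
    return out


def write_pf10_csv(path, pf10: np.ndarray) -> None:
    """PF-10 response matrix (n, 10) in the original 1-3 coding."""
    _write_matrix(path, PF10_COLUMNS, pf10)


def read_pf10_csv(path) -> np.ndarray:
    return _read_matrix(path, PF10_COLUMNS)


def write_haq_csv(path, haq_items: np.ndarray, aid_flags: np.ndarray) -> None:
    """HAQ-DI items (n, 20) plus per-category aid/device flags (n, 8)."""
    mat = np.hstack([np.asarray(haq_items, int), np.asarray(aid_flags, bool).astype(int)])
    _write_matrix(path, HAQ_ITEM_COLUMNS + AID_COLUMNS, mat)


def read_haq_csv(path) -> tuple[np.ndarray, np.ndarray]:
    mat = _read_matrix(path, HAQ_ITEM_COLUMNS + AID_COLUMNS)
    return mat[:, :20], mat[:, 20:].astype(bool)


# ---------------------------------------------------------------------------
# item parameter files (layout: one row per item, thresholds b1..b3,
# optional per-group fit columns)


def write_item_params(
    path, items: Sequence[ItemParams], fit: FitReport | None = None, metadata: Mapping | None = None
) -> None:
    max_b = max(it.thresholds.size for it in items)
    cols = ["item_id", "dimension", "n_categories", "discrimination"]
    cols += [f"b{h}" for h in range(1, max_b + 1)]
    if fit is not None:
        cols += ["es_low", "es_average", "es_high", "lm_statistic", "df", "p_value"]
        by_id = {r.item_id: r for r in fit.records}
    with open(path, "w", newline="") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        w = csv.writer(fh)
        w.writerow(cols)
        for it in items:
            row = [it.item_id, it.dimension, it.n_categories, repr(float(it.discrimination))]
            bs = [repr(float(b)) for b in it.thresholds]
            row += bs + [""] * (max_b - len(bs))
            if fit is not None:
                r = by_id[it.item_id]
                es = list(r.es) + [np.nan] * (3 - r.es.size)
                row += [repr(float(v)) for v in es]
                row += [repr(float(r.lm_statistic)), str(r.df), repr(float(r.p_value))]
            w.writerow(row)


def read_item_params(path) -> list[ItemParams]:
    items = []
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    header = rows[0]
    b_cols = [i for i, c in enumerate(header) if c.startswith("b") and c[1:].isdigit()]
    idx = {c: i for i, c in enumerate(header)}
    for row in rows[1:]:
        thresholds = [float(row[i]) for i in b_cols if i < len(row) and row[i] != ""]
        items.append(
            ItemParams(
                item_id=row[idx["item_id"]],
                dimension=int(row[idx["dimension"]]),
                discrimination=float(row[idx["discrimination"]]),
                thresholds=np.array(thresholds),
            )
        )
    return items


def write_fit_report(path, items: Sequence[ItemParams], fit: FitReport, metadata=None) -> None:
    """Item parameters with per-group fit statistics, one table."""
    meta = {"format": "pfhaqlink fit report v1", "es_cutoff": fit.cutoff, "passed": fit.passed}
    meta.update(metadata or {})
    write_item_params(path, items, fit=fit, metadata=meta)


# ---------------------------------------------------------------------------
# crosswalk tables


def write_crosswalk_csv(path, crosswalk: Crosswalk) -> None:
    """Serialize a crosswalk in the two-block concordance layout."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# {FORMAT_VERSION}\n")
        fh.write(f"# method: {crosswalk.method.value}\n")
        fh.write(f"# model: {crosswalk.model.value if crosswalk.model else ''}\n")
        for key, val in crosswalk.metadata.items():
            if key not in ("method", "model"):
                fh.write(f"# {key}: {val}\n")
        w = csv.writer(fh)
        has_eap = crosswalk.haq_eap is not None
        cols = ["method", "direction", "observed", "observed_norm", "predicted", "predicted_norm"]
        if has_eap:
            cols.append("observed_eap")
        w.writerow(cols)
        m = crosswalk.method.value
        for i, s in enumerate(crosswalk.observed_haq):
            row = [
                m,
                "haq_to_pf10",
                f"{s:.3f}",
                "",
                f"{crosswalk.predicted_pf10[i]:.0f}",
                f"{crosswalk.predicted_pf10_norm[i]:.1f}",
            ]
            if has_eap:
                row.append(repr(float(crosswalk.haq_eap[i])))
            w.writerow(row)
        order = np.argsort(-crosswalk.observed_pf10)  # published layout: best function first
        for i in order:
            row = [
                m,
                "pf10_to_haq",
                f"{crosswalk.observed_pf10[i]:.0f}",
                f"{crosswalk.observed_pf10_norm[i]:.1f}",
                f"{crosswalk.predicted_haq[i]:.3f}",
                "",
            ]
            if has_eap:
                row.append(repr(float(crosswalk.pf10_eap[i])))
            w.writerow(row)


def _parse_crosswalk_rows(lines: Iterable[str], method: HaqMethod) -> Crosswalk:
    meta: dict[str, str] = {}
    body = []
    for line in lines:
        if line.startswith("#"):
            text = line[1:].strip()
            if ":" in text:
                k, v = text.split(":", 1)
                meta[k.strip()] = v.strip()
            continue
        body.append(line)
    df = pd.read_csv(_io.StringIO("".join(body)), float_precision="round_trip")
    version = meta.get("", None)
    sub = df[df["method"] == method.value]
    if sub.empty:
        raise ValueError(f"no {method.value} block in crosswalk file")
    h2p = sub[sub["direction"] == "haq_to_pf10"].reset_index(drop=True)
    p2h = sub[sub["direction"] == "pf10_to_haq"].reset_index(drop=True)
    p2h = p2h.sort_values("observed").reset_index(drop=True)
    model = meta.get("model") or None
    return Crosswalk(
        method=method,
        model=ModelKind(model) if model else None,
        observed_haq=h2p["observed"].to_numpy(float),
        predicted_pf10=h2p["predicted"].to_numpy(float),
        predicted_pf10_norm=h2p["predicted_norm"].to_numpy(float),
        observed_pf10=p2h["observed"].to_numpy(float),
        observed_pf10_norm=p2h["observed_norm"].to_numpy(float),
        predicted_haq=p2h["predicted"].to_numpy(float),
        haq_eap=h2p["observed_eap"].to_numpy(float) if "observed_eap" in h2p else None,
        pf10_eap=p2h["observed_eap"].to_numpy(float) if "observed_eap" in p2h else None,
        metadata=meta,
    )


def read_crosswalk_csv(path, method: HaqMethod | str) -> Crosswalk:
    """Load one scoring-method block of a crosswalk file."""
    with open(path) as fh:
        first = fh.readline()
        if FORMAT_VERSION not in first:
            raise ValueError(
                f"{path}: unrecognized crosswalk format (expected '{FORMAT_VERSION}')"
            )
        return _parse_crosswalk_rows([first] + fh.readlines(), HaqMethod(method))


def load_published_crosswalk(method: HaqMethod | str = HaqMethod.SDI) -> Crosswalk:
    """The packaged published RA crosswalk (SDI or ADI block)."""
    ref = resources.files("pfhaqlink.data").joinpath("published_crosswalk.csv")
    with ref.open() as fh:
        return _parse_crosswalk_rows(fh.readlines(), HaqMethod(method))


def write_manifest(path, config: Mapping, seed: int | None = None) -> None:
    """Reproducibility manifest (config + seed) stored next to a dataset."""
    payload = {"config": dict(config), "seed": seed, "format": "pfhaqlink manifest v1"}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
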
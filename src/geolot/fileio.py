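"""Readers and writers for trials CSV, grammar config and result JSON.

Positions are 0-based everywhere (the alphabet is {0..7}); behavioural
datasets that label octagon vertices 1..8 must be shifted before loading.

The trials CSV has the header ``subject_id,trial_id,anchor,p1,...,pL``
(L <= 8, ragged rows padded with trailing blanks).  With
``anchor_mode="first_point"`` the file has no anchor column: the first
recorded point is taken as the anchor and the remaining points as the
sequence.

Result JSON is schema-versioned and records the grammar hash, config and
seed, so results from different grammars refuse to merge.
"""

from __future__ import annotations

import dataclasses
import gzip as gzip_mod
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .coding import CodingFit
from .enumeration import EnumerationResult
from .grammar import Grammar
from .inference import InferenceConfig, PosteriorResult, summarize_posterior
from .trials import Trial, TrialDataset

__all__ = [
    "read_trials",
    "write_trials",
    "read_grammar_config",
    "write_grammar_config",
    "write_results",
    "read_results",
    "load_posterior",
    "merge_posteriors",
]

SCHEMA_VERSION = 1


def _parse_position(value, row: int, column: str) -> int:
    try:
        pos = int(value)
    except (TypeError, ValueError):
        raise ValueError(f"row {row}: column {column!r} is not an integer: {value!r}")
    if not 0 <= pos <= 7:
        raise ValueError(f"row {row}: column {column!r} out of range 0..7: {pos}")
    return pos


def read_trials(path, anchor_mode: str = "explicit") -> TrialDataset:
    """Load a trials CSV.

    ``anchor_mode="explicit"`` expects an ``anchor`` column;
    ``"first_point"`` expects none and treats p1 as the anchor.
    """
    if anchor_mode not in ("explicit", "first_point"):
        raise ValueError(f"unknown anchor_mode {anchor_mode!r}")
    df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    if df.empty:
        raise ValueError(f"{path}: no trials")
    required = {"subject_id", "trial_id"}
    if anchor_mode == "explicit":
        required.add("anchor")
    elif "anchor" in df.columns:
        raise ValueError(
            f"{path}: file has an 'anchor' column; use anchor_mode='explicit'"
        )
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    point_cols = [c for c in df.columns if c.startswith("p") and c[1:].isdigit()]
    point_cols.sort(key=lambda c: int(c[1:]))
    if not point_cols:
        raise ValueError(f"{path}: no position columns p1..pL")

    trials = []
    seen: set[tuple[str, str]] = set()
    for i, row in df.iterrows():
        rownum = i + 2  # 1-based with header line
        points = []
        for c in point_cols:
            v = row[c]
            if pd.isna(v) or str(v).strip() == "":
                break
            points.append(_parse_position(v, rownum, c))
        if anchor_mode == "explicit":
            anchor = _parse_position(row["anchor"], rownum, "anchor")
            seq = points
        else:
            if len(points) < 2:
                raise ValueError(f"row {rownum}: first_point mode needs >= 2 points")
            anchor, seq = points[0], points[1:]
        if not seq:
            raise ValueError(f"row {rownum}: empty sequence")
        key = (str(row["subject_id"]), str(row["trial_id"]))
        if key in seen:
            raise ValueError(f"row {rownum}: duplicate trial id {key}")
        seen.add(key)
        trials.append(Trial(key[0], key[1], anchor, tuple(seq)))
    return TrialDataset(trials)


def write_trials(dataset: TrialDataset, path) -> None:
    df = dataset.to_frame()
    for c in df.columns:
        if c.startswith("p"):
            df[c] = df[c].astype("Int64")
    df.to_csv(path, index=False)


def read_grammar_config(path) -> Grammar:
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") else json.load(fh)
    return Grammar.from_config(cfg)


def write_grammar_config(grammar: Grammar, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix in (".yml", ".yaml"):
            yaml.safe_dump(grammar.config(), fh, sort_keys=True)
        else:
            json.dump(grammar.config(), fh, indent=2, sort_keys=True)


def _posterior_payload(result: PosteriorResult) -> dict:
    return {
        "kind": "posterior",
        "config": dataclasses.asdict(result.config),
        "production_ids": list(result.production_ids),
        "traces": result.traces.tolist(),
        "summary": {
            "mean": summarize_posterior(result)["mean"].to_dict(),
            "se": summarize_posterior(result)["se"].to_dict(),
        },
    }


def write_results(obj, path, grammar: Grammar | None = None, gzip: bool = False) -> None:
    """Write a result object (PosteriorResult, list of CodingFit, or list
    of EnumerationResult) as schema-versioned JSON (optionally gzipped)."""
    payload: dict = {"schema_version": SCHEMA_VERSION}
    if isinstance(obj, PosteriorResult):
        payload.update(_posterior_payload(obj))
        payload["grammar_hash"] = obj.grammar_hash
    elif isinstance(obj, (list, tuple)) and obj and isinstance(obj[0], CodingFit):
        payload["kind"] = "coding_fits"
        payload["fits"] = [f.to_dict() for f in obj]
    elif isinstance(obj, (list, tuple)) and all(
        isinstance(r, EnumerationResult) for r in obj
    ):
        payload["kind"] = "enumeration"
        payload["results"] = [
            {"anchor": r.anchor, "sequence": list(r.sequence), "count": r.count}
            for r in obj
        ]
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    if grammar is not None:
        payload["grammar_hash"] = grammar.hash()
        payload["grammar_config"] = grammar.config()
    blob = json.dumps(payload, sort_keys=True).encode()
    if gzip or str(path).endswith(".gz"):
        with gzip_mod.open(path, "wb") as fh:
            fh.write(blob)
    else:
        Path(path).write_bytes(blob)


def read_results(path) -> dict:
    if str(path).endswith(".gz"):
        with gzip_mod.open(path, "rb") as fh:
            return json.loads(fh.read())
    return json.loads(Path(path).read_bytes())


def load_posterior(path) -> PosteriorResult:
    data = read_results(path)
    if data.get("kind") != "posterior":
        raise ValueError(f"{path} does not hold a posterior result")
    cfg = InferenceConfig(**data["config"])
    return PosteriorResult(
        production_ids=tuple(data["production_ids"]),
        traces=np.array(data["traces"]),
        config=cfg,
        grammar_hash=data.get("grammar_hash", ""),
    )


def merge_posteriors(a: PosteriorResult, b: PosteriorResult) -> PosteriorResult:
    """Concatenate the chains of two runs over the same grammar/config."""
    if a.grammar_hash != b.grammar_hash:
        raise ValueError(
            f"refusing to merge results from different grammars "
            f"({a.grammar_hash} vs {b.grammar_hash})"
        )
    if a.production_ids != b.production_ids:
        raise ValueError("refusing to merge results with different production ids")
    if a.traces.shape[1] != b.traces.shape[1] or a.config.burn_in != b.config.burn_in:
        raise ValueError("refusing to merge results with different MCMC settings")
    return PosteriorResult(
        production_ids=a.production_ids,
        traces=np.concatenate([a.traces, b.traces], axis=0),
        config=dataclasses.replace(a.config, n_chains=a.config.n_chains + b.config.n_chains),
        grammar_hash=a.grammar_hash,
    )
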
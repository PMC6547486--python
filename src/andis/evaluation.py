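"""Benchmark metrics over decoy sets.

A decoy set is one native structure plus candidate models of the same
protein, optionally with an external quality score per model (TM-score or
GDT_TS from standard tools; this package does not compute them).  Metrics:

* native recognition — the native gets the strictly lowest energy;
* Z-score of the native — (<E_decoy> - E_native) / delta, population
  standard deviation, higher is better;
* PCC — Pearson correlation between decoy energies and quality scores
  (native excluded); negative is better since lower energy should mean
  higher quality;
* 20% enrichment — overlap of the best 20% by quality with the best 20%
  by energy, scaled so random ranking gives 1 and perfect agreement 5.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .scoring import ScoringConfig, score_structure
from .structure import ParseError, read_pdb

__all__ = [
    "DecoySetResult",
    "native_zscore",
    "recognize_native",
    "pcc",
    "enrichment20",
    "evaluate_set",
    "benchmark",
    "summarize",
]


@dataclass
class DecoySetResult:
    """Per-set energies joined to quality scores plus derived metrics."""

    set_id: str
    native_energy: float
    decoy_energies: np.ndarray
    quality_scores: np.ndarray | None = None
    z_score: float | None = None
    native_recognized: bool = False
    pcc: float | None = None
    enrichment20: float | None = None


def native_zscore(native_energy: float, decoy_energies) -> float | None:
    """(<E_decoy> - E_native) / delta; None when the spread is zero."""
    e = np.asarray(decoy_energies, dtype=float)
    if e.size < 2:
        raise ValueError("Z-score needs at least two decoys")
    delta = e.std()  # population convention
    if delta == 0:
        return None
    return float((e.mean() - native_energy) / delta)


def recognize_native(native_energy: float, decoy_energies) -> bool:
    """True iff the native energy is strictly below every decoy energy."""
    e = np.asarray(decoy_energies, dtype=float)
    return bool(e.size) and bool(native_energy < e.min())


def pcc(energies, quality_scores) -> float | None:
    """Pearson correlation between decoy energies and quality scores.

    None (undefined) when either vector has zero variance.
    """
    e = np.asarray(energies, dtype=float)
    q = np.asarray(quality_scores, dtype=float)
    if e.size != q.size:
        raise ValueError("energy and quality vectors differ in length")
    if e.size < 3:
        raise ValueError("PCC needs at least three decoys")
    if e.std() == 0 or q.std() == 0:
        return None
    return float(np.corrcoef(e, q)[0, 1])


def enrichment20(energies, quality_scores) -> float:
    """Relative occurrence of the top-20%-by-quality among the
    top-20%-by-energy, in [0, 5].

    With N decoys and k = max(1, floor(0.2 N)), the value is
    |top-k by quality intersect top-k by energy| * N / k^2; ties are broken
    by stable input order.
    """
    e = np.asarray(energies, dtype=float)
    q = np.asarray(quality_scores, dtype=float)
    if e.size != q.size:
        raise ValueError("energy and quality vectors differ in length")
    n = e.size
    if n < 5:
        raise ValueError("20% enrichment needs at least five decoys")
    k = max(1, int(np.floor(0.2 * n)))
    best_quality = np.argsort(-q, kind="stable")[:k]   # highest quality
    best_energy = np.argsort(e, kind="stable")[:k]     # lowest energy
    hits = len(set(best_quality.tolist()) & set(best_energy.tolist()))
    return hits * n / k ** 2


def evaluate_set(set_id: str, native_energy: float, decoy_energies,
                 quality_scores=None) -> DecoySetResult:
    """All metrics of one decoy set (natives excluded from PCC/enrichment)."""
    e = np.asarray(decoy_energies, dtype=float)
    result = DecoySetResult(
        set_id=set_id, native_energy=float(native_energy),
        decoy_energies=e,
        quality_scores=(None if quality_scores is None
                        else np.asarray(quality_scores, dtype=float)))
    result.z_score = native_zscore(native_energy, e)
    result.native_recognized = recognize_native(native_energy, e)
    if result.quality_scores is not None:
        result.pcc = pcc(e, result.quality_scores)
        result.enrichment20 = enrichment20(e, result.quality_scores)
    return result


def _read_scores(path: Path) -> dict[str, float]:
    """Two-column TSV model-id, score; a header line is optional."""
    scores: dict[str, float] = {}
    for line in path.read_text().splitlines():
        parts = line.strip().split("\t")
        if len(parts) < 2 or not parts[1]:
            continue
        try:
            scores[parts[0]] = float(parts[1])
        except ValueError:
            continue  # header
    return scores


def benchmark(decoy_root, potential, config: ScoringConfig | None = None,
              scores_name: str = "scores.tsv", native_name: str = "native.pdb",
              table=None, log=None) -> list[DecoySetResult]:
    """Score and evaluate every decoy-set folder under ``decoy_root``.

    Layout: one subdirectory per set holding ``native.pdb``, decoy ``*.pdb``
    files, and optionally a ``scores.tsv`` quality table keyed by decoy file
    stem.  Sets without a quality table get energies and Z-scores only.
    """
    log = log or (lambda msg: None)
    config = config or ScoringConfig()
    root = Path(decoy_root)
    results: list[DecoySetResult] = []
    for set_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        native_path = set_dir / native_name
        if not native_path.exists():
            log(f"{set_dir.name}: no {native_name}, skipped")
            continue
        try:
            native = read_pdb(native_path, table=table)
        except ParseError as exc:
            log(f"{set_dir.name}: {exc}")
            continue
        native_energy = score_structure(native, potential, config,
                                        table=table).energy
        decoy_ids, energies = [], []
        for decoy_path in sorted(set_dir.glob("*.pdb")):
            if decoy_path.name == native_name:
                continue
            try:
                decoy = read_pdb(decoy_path, table=table)
            except ParseError as exc:
                log(f"{set_dir.name}/{decoy_path.name}: {exc}")
                continue
            decoy_ids.append(decoy_path.stem)
            energies.append(score_structure(decoy, potential, config,
                                            table=table).energy)
        if len(energies) < 2:
            log(f"{set_dir.name}: fewer than two decoys, skipped")
            continue
        quality = None
        scores_path = set_dir / scores_name
        if scores_path.exists():
            scores = _read_scores(scores_path)
            if all(d in scores for d in decoy_ids):
                quality = np.array([scores[d] for d in decoy_ids])
            else:
                log(f"{set_dir.name}: quality table incomplete; "
                    "PCC/enrichment skipped")
        results.append(evaluate_set(set_dir.name, native_energy,
                                    np.array(energies), quality))
    return results


def summarize(results: list[DecoySetResult]) -> pd.DataFrame:
    """One-row-per-set table in the shape of a benchmark summary."""
    rows = []
    for r in results:
        rows.append({
            "set_id": r.set_id,
            "n_decoys": r.decoy_energies.size,
            "native_energy": r.native_energy,
            "recognized": r.native_recognized,
            "z_score": r.z_score,
            "pcc": r.pcc,
            "enrichment20": r.enrichment20,
        })
    return pd.DataFrame(rows)
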
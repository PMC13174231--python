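"""Shared fixtures and independent metric oracles for the test suite."""

from __future__ import annotations

import math

import pytest

from iraescan import load_builtin_profile


@pytest.fixture(scope="session")
def demo_profile():
    """Five disjoint labels over four organ categories; the simulation default."""
    return load_builtin_profile("demo")


@pytest.fixture(scope="session")
def vumc_profile():
    return load_builtin_profile("vumc")


@pytest.fixture(scope="session")
def ucsf_profile():
    return load_builtin_profile("ucsf")


# ---------------------------------------------------------------------------
# Independent brute-force oracle: computes every metric cell-by-cell from the
# raw unit/label matrix, entirely separate from the package implementation.
# ---------------------------------------------------------------------------


def oracle_confusion(pred: dict, gold: dict, labels: list[str]) -> dict:
    out = {}
    for lab in labels:
        tp = sum(1 for u in pred if lab in pred[u] and lab in gold[u])
        fp = sum(1 for u in pred if lab in pred[u] and lab not in gold[u])
        fn = sum(1 for u in pred if lab not in pred[u] and lab in gold[u])
        tn = sum(1 for u in pred if lab not in pred[u] and lab not in gold[u])
        out[lab] = (tp, fp, fn, tn)
    return out


def oracle_prsf(tp: int, fp: int, fn: int, tn: int) -> dict:
    p = tp / (tp + fp) if tp + fp else math.nan
    r = tp / (tp + fn) if tp + fn else math.nan
    s = tn / (tn + fp) if tn + fp else math.nan
    if tp == 0 and fp == 0 and fn == 0:
        f1 = math.nan
    elif tp == 0:
        f1 = 0.0
    else:
        f1 = 2 * p * r / (p + r)
    return {"P": p, "R": r, "S": s, "F1": f1}


def oracle_metrics(counts: dict) -> dict:
    """Per-label rows plus pooled micro row and NA-excluding macro row."""
    rows = {lab: oracle_prsf(*c) for lab, c in counts.items()}
    pooled = tuple(sum(c[i] for c in counts.values()) for i in range(4))
    rows["micro avg"] = oracle_prsf(*pooled)
    macro = {}
    for col in ("P", "R", "S", "F1"):
        vals = [rows[lab][col] for lab in counts if not math.isnan(rows[lab][col])]
        macro[col] = sum(vals) / len(vals) if vals else math.nan
    rows["macro avg"] = macro
    return rows


def assert_close_or_both_nan(a: float, b: float, tol: float = 1e-12) -> None:
    if math.isnan(a) or math.isnan(b):
        assert math.isnan(a) and math.isnan(b), f"NA mismatch: {a} vs {b}"
    else:
        assert abs(a - b) <= tol, f"{a} vs {b}"
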
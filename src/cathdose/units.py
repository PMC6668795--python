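"""Unit dialects for dose quantities.

Vendors export dose-area product (DAP, strictly air kerma-area product) in a
zoo of units; everything inside this package is canonical:

* DAP in cGy·cm²
* air kerma in mGy
* durations in seconds (minutes only at reporting boundaries)
"""
from __future__ import annotations

# multiplier: value_in_dialect * factor -> cGy·cm²
DAP_DIALECTS = {
    "cGy.cm2": 1.0,
    "Gy.cm2": 100.0,
    "mGy.cm2": 0.1,
    "uGy.m2": 1.0,      # 1 µGy·m² = 1e-6 Gy · 1e4 cm² = 1 cGy·cm²
    "Gy.m2": 1.0e6,
    "mGy.m2": 1.0e3,
}

# multiplier: value_in_dialect * factor -> mGy
KERMA_DIALECTS = {
    "mGy": 1.0,
    "Gy": 1000.0,
    "cGy": 10.0,
    "uGy": 1.0e-3,
}


def dap_to_canonical(value: float, dialect: str) -> float:
    """Convert a DAP value from *dialect* to cGy·cm²."""
    try:
        return value * DAP_DIALECTS[dialect]
    except KeyError:
        raise ValueError(
            f"unknown DAP dialect {dialect!r}; known: {sorted(DAP_DIALECTS)}"
        ) from None


def dap_from_canonical(value: float, dialect: str) -> float:
    """Convert a canonical cGy·cm² DAP value to *dialect*."""
    try:
        return value / DAP_DIALECTS[dialect]
    except KeyError:
        raise ValueError(
            f"unknown DAP dialect {dialect!r}; known: {sorted(DAP_DIALECTS)}"
        ) from None


def kerma_to_canonical(value: float, dialect: str) -> float:
    """Convert an air-kerma value from *dialect* to mGy."""
    try:
        return value * KERMA_DIALECTS[dialect]
    except KeyError:
        raise ValueError(
            f"unknown kerma dialect {dialect!r}; known: {sorted(KERMA_DIALECTS)}"
        ) from None
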
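"""Synthetic Ct tables for the TSDR demethylation assay.

Inverts the demethylation formula to manufacture methylation-/
demethylation-specific Ct pairs whose noiseless transform returns a
chosen true demethylation fraction; Gaussian cycle noise can be layered
on both reactions to emulate replicate scatter.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["synth_tsdr", "delta_ct_for_fraction"]


def delta_ct_for_fraction(true_fraction: float) -> float:
    """ΔCt = Ct(methylation) − Ct(demethylation) that yields ``true_fraction`` %.

    Algebraic inverse of ``100 / (1 + 2**ΔCt)``; fractions of 0 or 100
    would need infinite ΔCt and are rejected.
    """
    if not 0.0 < true_fraction < 100.0:
        raise ValueError(
            f"true_fraction must lie strictly in (0, 100), got {true_fraction}"
        )
    return float(np.log2(100.0 / true_fraction - 1.0))


def synth_tsdr(
    true_fraction: float,
    ct_base: float = 28.0,
    noise_sd: float = 0.0,
    n: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate ``n`` Ct pairs for one true demethylation percentage.

    ``ct_base`` is the demethylation-specific Ct before noise (cycles);
    the methylation-specific Ct is offset by the exact ΔCt for
    ``true_fraction``.  Independent N(0, noise_sd) cycle noise is added
    to each reaction.  Columns: ``sample_id, ct_meth, ct_demeth,
    true_fraction``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    dct = delta_ct_for_fraction(true_fraction)
    rng = np.random.default_rng(seed)
    ct_demeth = ct_base + rng.normal(0.0, noise_sd, size=n) if noise_sd else np.full(n, ct_base)
    ct_meth = ct_base + dct + (rng.normal(0.0, noise_sd, size=n) if noise_sd else 0.0)
    return pd.DataFrame(
        {
            "sample_id": [f"synth_{i:04d}" for i in range(n)],
            "ct_meth": ct_meth,
            "ct_demeth": ct_demeth,
            "true_fraction": true_fraction,
        }
    )
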
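"""Chain diagnostics: effective sample size and replicate agreement.

The ESS follows the common trace-viewer convention: the autocorrelation
function is summed term by term until the first nonpositive estimate, and
ESS = n / (1 + 2 * sum(rho_k)), capped at n.  A run passes only when every
(non-constant) parameter reaches the ESS threshold in both replicates and
the replicate means agree within two combined Monte-Carlo standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dating_engine import PosteriorTrace

ESS_THRESHOLD = 200


class ConstantSeriesError(ValueError):
    """ESS is undefined for a constant series (zero variance)."""


class TraceSchemaError(ValueError):
    """Replicate traces do not share a parameter schema."""


def ess(samples: Sequence[float] | np.ndarray) -> float:
    """Effective sample size of an autocorrelated numeric series."""
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError(f"need at least 10 samples, got {n}")
    if np.ptp(x) == 0.0:
        raise ConstantSeriesError("ESS is undefined for a constant series")
    x = x - x.mean()
    var = float(x @ x) / n
    if var == 0.0 or not np.isfinite(var):
        raise ConstantSeriesError("ESS is undefined for a constant series")
    # FFT autocovariance, biased normalization (divide by n)
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conjugate(f), m)[:n].real / n
    rho = acov / acov[0]
    total = 0.0
    for k in range(1, n):
        if rho[k] <= 0.0:
            break
        total += rho[k]
    return float(min(n, n / (1.0 + 2.0 * total)))


@dataclass
class DiagnosticsReport:
    per_parameter: pd.DataFrame  # parameter, ess_1, ess_2, mean_1, mean_2, agree, ok
    passed: bool
    extension_factor: int
    skipped_constant: list[str] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# passed={self.passed} extension_factor={self.extension_factor} "
                f"skipped_constant={','.join(self.skipped_constant) or '-'}\n"
            )
            self.per_parameter.to_csv(fh, sep="\t", index=False)


def check_and_extend(
    trace_pair: tuple[PosteriorTrace, PosteriorTrace] | Sequence[PosteriorTrace],
    threshold: int = ESS_THRESHOLD,
) -> DiagnosticsReport:
    """Two-replicate convergence check with the ESS >= threshold rerun rule.

    A parameter fails when its ESS is below ``threshold`` in either
    replicate; node ages additionally require
    ``|mean1 - mean2| <= 2 * sqrt(var1/ESS1 + var2/ESS2)``.  Failing reports
    carry ``extension_factor = ceil(threshold / min ESS)`` — the factor by
    which the chains should be extended before rechecking.
    """
    if len(trace_pair) != 2:
        raise ValueError("exactly two replicate traces are required")
    t1, t2 = trace_pair
    cols1 = [c for c in t1.samples.columns if c != "state"]
    cols2 = [c for c in t2.samples.columns if c != "state"]
    if cols1 != cols2:
        raise TraceSchemaError(
            f"replicate schemas differ: {sorted(set(cols1) ^ set(cols2))}"
        )
    rows = []
    skipped = []
    min_ess = math.inf
    all_ok = True
    for col in cols1:
        x1 = t1.samples[col].to_numpy()
        x2 = t2.samples[col].to_numpy()
        if np.ptp(x1) == 0.0 and np.ptp(x2) == 0.0:
            skipped.append(col)
            continue
        try:
            e1, e2 = ess(x1), ess(x2)
        except ConstantSeriesError:
            skipped.append(col)
            continue
        m1, m2 = float(x1.mean()), float(x2.mean())
        v1, v2 = float(x1.var(ddof=1)), float(x2.var(ddof=1))
        ess_ok = e1 >= threshold and e2 >= threshold
        if col.startswith("t_"):
            se = math.sqrt(v1 / e1 + v2 / e2)
            agree = abs(m1 - m2) <= 2.0 * se
        else:
            agree = True
        ok = ess_ok and agree
        all_ok &= ok
        min_ess = min(min_ess, e1, e2)
        rows.append({
            "parameter": col, "ess_1": e1, "ess_2": e2,
            "mean_1": m1, "mean_2": m2, "agree": agree, "ok": ok,
        })
    if not rows:
        raise TraceSchemaError("no non-constant parameters to diagnose")
    factor = 1 if all_ok else int(math.ceil(threshold / max(min_ess, 1e-12)))
    return DiagnosticsReport(pd.DataFrame(rows), bool(all_ok), max(1, factor), skipped)
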
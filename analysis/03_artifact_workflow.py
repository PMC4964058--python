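"""Blooming-artifact workflow: inject, detect, exclude, refit.

Builds a noisy post-contrast myocardial decay series (true R2* =
60.5 s^-1, first-echo SNR 20), corrupts echoes 4-8 with a blooming-style
extra attenuation, runs the automated late-echo detector, and compares
the corrupted fit with the refit after exclusion.  Repeats over 500
replicates and writes the summary to results/artifact_summary.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from uspio_t2star import DEFAULT_ECHO_TIMES_MS, EchoSeries, fit_loglinear
from uspio_t2star.artifact_qc import detect_artifact_echoes
from uspio_t2star.phantom import decay_signal

OUT = Path("results")
TRUTH = 60.5       # s^-1, post-contrast myocardium at 1.5 T
SEVERITY = 150.0   # extra s^-1 inside the artifact from echo 4 onward
SNR = 20.0
N_REP = 500


def main() -> None:
    te = np.array(DEFAULT_ECHO_TIMES_MS)
    clean = np.asarray(decay_signal(1000.0, TRUTH, te))
    corrupted = clean.copy()
    corrupted[3:] *= np.exp(-te[3:] * SEVERITY / 1000.0)
    sigma = clean[0] / SNR
    rng = np.random.default_rng(42)

    rows = []
    for rep in range(N_REP):
        g1 = rng.normal(0, sigma, 8)
        g2 = rng.normal(0, sigma, 8)
        series = EchoSeries(te, np.sqrt((corrupted + g1) ** 2 + g2**2),
                            background_sigma=sigma)
        report = detect_artifact_echoes(series, allow_relaxed=True)
        naive = fit_loglinear(series)
        rows.append({
            "replicate": rep,
            "n_flagged": int(report.flagged_echoes.sum()),
            "detected": report.any_flagged,
            "r2star_naive": naive.r2star if naive.valid else np.nan,
            "r2star_refit": report.refit.r2star if report.refit.valid else np.nan,
            "rsq_before": report.r_squared_before,
            "rsq_after": report.r_squared_after,
        })
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "artifact_summary.csv", index=False)

    det = df.detected.mean()
    err_naive = (df.r2star_naive - TRUTH).abs().median()
    err_refit = (df.r2star_refit - TRUTH).abs().median()
    print(f"true R2* {TRUTH} s^-1, blooming +{SEVERITY} s^-1 from echo 4, SNR {SNR:.0f}")
    print(f"detection rate: {det:.1%} ({N_REP} replicates)")
    print(f"median |error|: naive fit {err_naive:.1f} s^-1 "
          f"-> refit after exclusion {err_refit:.1f} s^-1")
    print(f"median r^2: before {df.rsq_before.median():.3f} "
          f"-> after {df.rsq_after.median():.3f}")
    print(f"table -> {OUT/'artifact_summary.csv'}")


if __name__ == "__main__":
    main()
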
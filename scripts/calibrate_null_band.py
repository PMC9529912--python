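"""Calibrate the chance band for the false-positive control.

Brute-force null oracle: k = 2 clustering of spherical Gaussian point
clouds of matched size and dimension, compared with random balanced labels
under the best label mapping.  Because the labels are independent of the
data, the agreement exceeds 50% in finite samples purely by the
combinatorics of balanced partitions; this script measures that baseline
and freezes it into the package resource ``resources/null_band.json``.

The oracle deliberately uses scikit-learn's KMeans, not the package's own
clustering, so the stored band is independent of the implementation it
later judges.

Usage: python scripts/calibrate_null_band.py [--trials 20000]
"""
from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

RESOURCE = Path(__file__).resolve().parents[1] / "src" / "phenoclust" / "resources" / "null_band.json"

#: (n animals, clustering dimension) pairs to calibrate.
CASES = [(36, 2), (36, 1)]


def oracle_accuracy(n: int, d: int, trials: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    accs = np.empty(trials)
    half = n // 2
    for t in range(trials):
        X = rng.standard_normal((n, d))
        km = KMeans(n_clusters=2, n_init=10,
                    random_state=int(rng.integers(2**31 - 1))).fit(X)
        labels = km.labels_
        truth = np.zeros(n, dtype=int)
        truth[rng.permutation(n)[:half]] = 1
        agree = int((labels == truth).sum())
        accs[t] = 100.0 * max(agree, n - agree) / n
    return accs


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--trials", type=int, default=20000)
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()
    entries = []
    for n, d in CASES:
        accs = oracle_accuracy(n, d, args.trials, args.seed)
        entries.append({
            "n": n,
            "n_pcs": d,
            "oracle_trials": args.trials,
            "mean": round(float(accs.mean()), 4),
            "sd": round(float(accs.std(ddof=1)), 4),
            "q025": round(float(np.quantile(accs, 0.025)), 4),
            "q975": round(float(np.quantile(accs, 0.975)), 4),
        })
        print(entries[-1])
    RESOURCE.write_text(json.dumps(entries, indent=2), encoding="utf-8")
    print(f"wrote {RESOURCE}")


if __name__ == "__main__":
    main()
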
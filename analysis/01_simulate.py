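#!/usr/bin/env python
"""Generate the synthetic three-class spectral dataset.

Renders the train/test surrogate of the authentication experiment — 60
training and 100 test spectra per class under the default noise
conditions — and writes a dataset summary plus one example spectrum per
class under results/.  Pass --spectra-dir to also dump every spectrum as
a two-column CSV with a labels manifest (large; off by default).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import ftirclass as fc

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-train", type=int, default=60)
    ap.add_argument("--n-test", type=int, default=100)
    ap.add_argument("--spectra-dir", type=Path, default=None)
    args = ap.parse_args()
    RESULTS.mkdir(exist_ok=True)

    train = fc.generate_dataset(args.n_train, fc.NoiseModel(seed=args.seed))
    test = fc.generate_dataset(args.n_test, fc.NoiseModel(seed=args.seed + 1))

    rows = []
    for split, ds in (("train", train), ("test", test)):
        labels = np.array(ds.labels)
        for c in ds.classes:
            sel = np.vstack([s.absorbance for s in ds if s.label == c])
            rows.append({
                "split": split, "class": c, "n": int((labels == c).sum()),
                "mean_absorbance": sel.mean(), "max_absorbance": sel.max(),
            })
    summary = pd.DataFrame(rows)
    summary.to_csv(RESULTS / "dataset_summary.csv", index=False)
    print(summary.to_string(index=False))

    for t in fc.default_templates():
        spec = fc.render_spectrum(t, noise=fc.NoiseModel(seed=args.seed))
        fc.write_spectrum(spec, RESULTS / f"example_{t.name}.csv")
    print(f"wrote dataset summary and 3 example spectra to {RESULTS}")

    if args.spectra_dir:
        args.spectra_dir.mkdir(parents=True, exist_ok=True)
        manifest = []
        for split, ds in (("train", train), ("test", test)):
            for i, s in enumerate(ds):
                name = f"{split}_{i:04d}.csv"
                fc.write_spectrum(s, args.spectra_dir / name)
                manifest.append({"file": name, "split": split, "label": s.label})
        pd.DataFrame(manifest).to_csv(args.spectra_dir / "labels.csv", index=False)
        print(f"wrote {len(manifest)} spectra to {args.spectra_dir}")


if __name__ == "__main__":
    main()
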
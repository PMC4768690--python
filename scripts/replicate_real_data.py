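#!/usr/bin/env python
"""Re-run the full otolith identification experiment on real photographs.

The published per-family accuracies were obtained from photographs of right
sagittal otoliths (proximal view) of 14 species from the Sciaenidae,
Ariidae and Engraulidae families. Those images are not distributed with
this package; if you have them (they are available as supplementary data of
the original study), arrange them as one directory per species::

    data/
      Coilia_dussumieri/*.png|tif|jpg
      Setipinna_taty/...
      ...

and run::

    python scripts/replicate_real_data.py data/ --n-train 18 --n-test 10

For each species the first ``--n-train`` images (sorted by filename) train
the discriminant model and the next ``--n-test`` are held out for testing;
the confusion matrix and overall accuracy are printed. No pass/fail gate is
attached: real-image results depend on photographic conditions and will not
exactly match any published number.
"""

import argparse
import sys
from pathlib import Path

import numpy as np


def main(argv=None) -> int:
    parser = argparse.ArgumentParser(
        description=__doc__, formatter_class=argparse.RawDescriptionHelpFormatter
    )
    parser.add_argument("data_dir", type=Path, help="directory of per-species image folders")
    parser.add_argument("--n-train", type=int, default=18, help="training images per species")
    parser.add_argument("--n-test", type=int, default=10, help="test images per species")
    parser.add_argument("--window-kind", default="gaussian")
    parser.add_argument("--feature-set", default="combined",
                        choices=["abs_only", "ang_only", "combined"])
    parser.add_argument("--ridge", type=float, default=0.0)
    args = parser.parse_args(argv)

    from otolithid import LabelledFeatures, RunConfig, evaluate, load_image, train_da
    from otolithid.pipeline import image_to_features
    from otolithid.spectral import feature_names

    cfg = RunConfig(window_kind=args.window_kind, feature_set=args.feature_set,
                    ridge=args.ridge)
    exts = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}
    species_dirs = sorted(d for d in args.data_dir.iterdir() if d.is_dir())
    if not species_dirs:
        print(f"no species directories found under {args.data_dir}", file=sys.stderr)
        return 1

    X_train, y_train, X_test, y_test = [], [], [], []
    for d in species_dirs:
        images = sorted(p for p in d.iterdir() if p.suffix.lower() in exts)
        need = args.n_train + args.n_test
        if len(images) < need:
            print(f"warning: {d.name} has {len(images)} images, need {need}; skipped",
                  file=sys.stderr)
            continue
        for i, path in enumerate(images[:need]):
            try:
                fv = image_to_features(load_image(path), cfg).combined
            except Exception as exc:  # per-image failures are reported, not fatal
                print(f"warning: {path} failed: {exc}", file=sys.stderr)
                continue
            if i < args.n_train:
                X_train.append(fv); y_train.append(d.name)
            else:
                X_test.append(fv); y_test.append(d.name)

    if not X_train or not X_test:
        print("no usable images", file=sys.stderr)
        return 1
    if cfg.feature_set != "combined":
        names = feature_names(16, "combined")
        keep = [names.index(n) for n in feature_names(16, cfg.feature_set)]
        X_train = [x[keep] for x in X_train]
        X_test = [x[keep] for x in X_test]
    model = train_da(
        LabelledFeatures(X=np.array(X_train), labels=np.array(y_train)),
        ridge=args.ridge,
    )
    result = evaluate(model, LabelledFeatures(X=np.array(X_test), labels=np.array(y_test)))
    print(result.confusion.summary())
    return 0


if __name__ == "__main__":
    sys.exit(main())
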
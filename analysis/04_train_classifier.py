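#!/usr/bin/env python
"""Train the multi-input echo-spectrogram CNN on the simulated study.

Builds echo chunks from the scan container (spectrograms are rendered on
demand from impulse response + bat call), trains the shared-branch CNN with
Adam/early stopping, and reports test accuracy, the confusion matrix and
per-syndrome accuracies with exact binomial confidence intervals.

The defaults are scaled for a quick desk run (k=3, random sampling, the
reduced-angle scans from 01_simulate_study.py); pass --epochs/--k to explore.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from floralecho import io
from floralecho.echonet import (
    EchoCNN,
    EchoRenderer,
    Hyper,
    build_chunks,
    evaluate,
    split_by_flower,
    train,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--k", type=int, default=3, choices=(1, 3, 5, 7, 10))
    ap.add_argument("--scheme", default="random", choices=("random", "interval"))
    ap.add_argument("--epochs", type=int, default=15)
    ap.add_argument("--lr", type=float, default=1e-3)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--echo-len", type=int, default=1536)
    args = ap.parse_args()

    scans, meta = io.read_scans_h5(ROOT / "scratch" / "scans.h5")
    call, rate = io.read_wav(ROOT / "scratch" / "call.wav")
    species_by_flower = dict(zip(meta["flower_id"], meta["species_id"]))
    syndromes = dict(zip(meta["species_id"], meta["syndrome"]))
    by_species: dict = {}
    for fid, sp in species_by_flower.items():
        by_species.setdefault(sp, []).append(fid)
    split = split_by_flower(by_species, counts=(8, 2, 2), seed=args.seed)
    class_order = sorted(by_species)

    renderer = EchoRenderer(scans, call, rate, echo_len=args.echo_len)
    chunks = {
        part: build_chunks(scans, species_by_flower, split.ids(part),
                           args.k, args.scheme, args.seed + i)
        for i, part in enumerate(("train", "val", "test"))
    }
    print(f"{len(class_order)} classes; chunks: " +
          ", ".join(f"{p}={len(c)}" for p, c in chunks.items()))

    model = EchoCNN(renderer.shape, args.k, n_classes=len(class_order),
                    seed=args.seed)
    hyper = Hyper(epochs=args.epochs, learning_rate=args.lr, patience=6,
                  seed=args.seed)
    report = train(model, chunks["train"], chunks["val"], renderer,
                   class_order, hyper)
    report = evaluate(model, chunks["test"], renderer, class_order,
                      syndromes, report=report)

    (ROOT / "results").mkdir(exist_ok=True)
    (ROOT / "results" / "train_report.json").write_text(report.to_json())
    np.savetxt(ROOT / "results" / "confusion.csv", report.confusion,
               fmt="%d", delimiter=",", header=",".join(class_order))
    model.save(ROOT / "scratch" / "echonet.npz")

    print(f"trained {report.epochs_run} epochs (early stop: {report.early_stopped})")
    print(f"test accuracy: {report.test_accuracy:.3f}")
    for syn, d in report.per_syndrome.items():
        print(f"  {syn}: {d['accuracy']:.3f} "
              f"(95% CI {d['ci_low']:.3f}-{d['ci_high']:.3f}, n={d['n']})")


if __name__ == "__main__":
    main()
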
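"""Tuning script for the synthetic-cohort spectral constants.

Prints the analyzer's median features for a candidate SynthClassSpec next to
the published reference column, so the knee / hf_fraction / dispersion
constants in ``default_class_specs`` can be chosen. Run from the repo root:

    python scripts/calibrate_synth.py [n_records] [--class regular|preshock]
    python scripts/calibrate_synth.py --sweep   # small knob sweep

The frozen defaults in ``vtwarn.synth.default_class_specs`` were chosen with
this script; re-run it after any generator change.
"""

from __future__ import annotations

import argparse
from dataclasses import replace

import numpy as np
import pandas as pd

from vtwarn.features import SCALAR_FEATURES, extract_feature_row
from vtwarn.records import (
    WindowTooShortError,
    extract_pre_event_window,
    filter_ectopic_beats,
)
from vtwarn.synth import TABLE_REFERENCE, default_class_specs, generate_tachogram


def feature_medians(spec, n_records=100, seed=0, horizon="five_minute", n_beats=2048):
    rng = np.random.default_rng(seed)
    rows = []
    skipped = 0
    for i in range(n_records):
        rec = generate_tachogram(spec, n_beats, rng, record_id=f"r{i}")
        try:
            w = extract_pre_event_window(filter_ectopic_beats(rec), horizon)
        except WindowTooShortError:
            skipped += 1  # mirrors the pipeline's exclusion of shredded records
            continue
        rows.append(
            extract_feature_row(w, {"record_id": f"r{i}", "label": spec.label}).as_dict()
        )
    if skipped:
        print(f"  ({spec.label}: {skipped}/{n_records} records excluded)")
    df = pd.DataFrame(rows)
    return df[SCALAR_FEATURES].median()


def report(spec, n_records, seed=0):
    med = feature_medians(spec, n_records, seed)
    ref = TABLE_REFERENCE["five_minute"]
    print(f"-- {spec.label}: gamma={spec.gamma} knee={spec.f_knee} "
          f"knee_exp={spec.knee_exponent} hf={spec.hf_fraction} "
          f"sd={spec.fluctuation_sd_scale} --")
    for f in SCALAR_FEATURES:
        r = ref[f][spec.label][0]
        print(f"  {f:18s} synth={med[f]:10.4g}  ref={r:10.4g}  ratio={med[f]/r:6.2f}")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("n", nargs="?", type=int, default=100)
    ap.add_argument("--class", dest="cls", default="both",
                    choices=["regular", "preshock", "both"])
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--sweep", action="store_true")
    ap.add_argument("--set", nargs="*", default=[],
                    help="field=value overrides, e.g. hf_fraction=0.005")
    args = ap.parse_args()

    reg, pre = default_class_specs()
    overrides = {}
    for kv in args.set:
        k, v = kv.split("=")
        overrides[k] = float(v)
    if args.sweep:
        for knee in (0.03, 0.04, 0.05):
            for hf in (0.001, 0.003, 0.01):
                report(replace(reg, f_knee=knee, hf_fraction=hf,
                               gamma_sd=0, hf_dispersion=0, fluctuation_sd_sigma=0),
                       args.n, args.seed)
        return
    if args.cls in ("regular", "both"):
        report(replace(reg, **overrides), args.n, args.seed)
    if args.cls in ("preshock", "both"):
        report(replace(pre, **overrides), args.n, args.seed)


if __name__ == "__main__":
    main()
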
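#!/usr/bin/env python
"""Compute the vertebrate shape index (VSI) and its four summands for
every specimen in the fixture, and report the group means — extinct
eels should score lower, having fewer vertebrae with shorter centra."""

import argparse
from pathlib import Path

import pandas as pd

from eelmorph import compute_vsi
from eelmorph import io as emio


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fixture", type=Path, default=Path("results/fixture"))
    ap.add_argument("--out", type=Path, default=Path("results/vsi.csv"))
    args = ap.parse_args()

    records = emio.read_specimen_table(args.fixture / "specimens.csv")
    rows = []
    for rec in records:
        r = compute_vsi(rec)
        rows.append({
            "taxon_id": r.taxon_id, "status": rec.status, "vsi": r.vsi,
            "term_ratio": r.term_ratio, "term_head": r.term_head,
            "term_pcv": r.term_pcv, "term_cv": r.term_cv,
        })
    df = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out, index=False, float_format="%.3f")
    means = df.groupby("status")["vsi"].mean()
    print(f"wrote per-taxon VSI for {len(df)} specimens to {args.out}")
    for status, m in means.items():
        print(f"  mean VSI ({status}): {m:.1f}")


if __name__ == "__main__":
    main()
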
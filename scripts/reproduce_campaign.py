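"""Shannon-model sensitivity campaign at configurable scale.

This drives the same library pipeline as the desk-scale runs, but against
the paced ODE model over the normal-response box: Saltelli design with
second-order blocks, final-beat biomarkers, Jansen indices with bootstrap
CIs, grand-total ranking, and the reduced-model hierarchy.  At the
paper-scale settings (M = 8192, 1000-beat trains, L = 2000) this is a
multi-day single-CPU campaign — run it scaled down (e.g. --m 64
--beats 200) or on many cores via a shared cache directory.

Also optionally reproduces the one-at-a-time pNaK normal-range scan
(--scan pNaK), whose upper boundary is reported alongside.

Example (small overnight run):
    python scripts/reproduce_campaign.py --m 256 --beats 200 \
        --bootstrap 1000 --l 500 --out-dir results/campaign
"""

from __future__ import annotations

import argparse
import json
import os
import sys


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--m", type=int, default=1024, help="base sample size")
    ap.add_argument("--beats", type=int, default=200,
                    help="pre-pacing train length per evaluation")
    ap.add_argument("--bootstrap", type=int, default=1000)
    ap.add_argument("--l", type=int, default=500, help="reduction sample size")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--ca", action="store_true",
                    help="include the four calcium biomarkers")
    ap.add_argument("--scan", default=None, metavar="PARAM",
                    help="also run the one-at-a-time normal-range scan for "
                         "this scaling factor (e.g. pNaK)")
    ap.add_argument("--out-dir", default="results/campaign")
    ap.add_argument("--cache", default=None,
                    help="JSON-lines evaluation cache (checkpoint/resume)")
    args = ap.parse_args(argv)

    from apsens.pipeline import RunConfig, run_pipeline

    cfg = RunConfig(
        M=args.m, n_beats=args.beats, bootstrap_reps=args.bootstrap,
        L=args.l, seed=args.seed, second_order=True,
        use_ca_biomarkers=args.ca, failure_mode="tolerant",
        cache_path=args.cache, out_dir=args.out_dir,
    )
    result = run_pipeline(cfg, model="shannon")

    print("grand ranking:", " > ".join(result.ranking.names))
    d = result.sobol.per_output["A90"]
    i_clb = result.sobol.param_names.index("pClb")
    print(f"pClb on A90: S1 = {d['S1'][i_clb]:.3f} "
          f"(+-{d['S1_half_width'][i_clb]:.3f}), "
          f"ST = {d['ST'][i_clb]:.3f} (+-{d['ST_half_width'][i_clb]:.3f})")
    if "S2" in d:
        i_kr = result.sobol.param_names.index("pKr")
        print(f"(pKr,pClb) on A90: S2 = {d['S2'][i_kr, i_clb]:.3f} "
              f"(+-{d['S2_half_width'][i_kr, i_clb]:.3f})")
    print(result.reduction.levels.to_string(index=False))

    if args.scan:
        from apsens.region import scan_normal_range
        from apsens.shannon import PacingProtocol, ScalingVector
        scan = scan_normal_range(args.scan, ScalingVector(),
                                 PacingProtocol(n_beats=args.beats))
        lo, hi = scan.normal_interval
        print(f"{args.scan} normal 1:1 interval: [{lo:.2f}, {hi:.2f}]")
        scan.to_csv(os.path.join(args.out_dir, f"scan_{args.scan}.csv"))
    return 0


if __name__ == "__main__":
    sys.exit(main())
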
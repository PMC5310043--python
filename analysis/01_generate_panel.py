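"""Generate and validate the synthetic survey panel."""

import argparse

from reefcarb.pipeline import load_config, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--config", default=None)
    ap.add_argument("--seed", type=int, default=None)
    ap.add_argument("--outdir", default="results/run")
    args = ap.parse_args()
    run_pipeline(load_config(args.config), stages=("simulate", "validate"),
                 outdir=args.outdir, seed=args.seed)
    print(f"census tables written under {args.outdir}/data")


if __name__ == "__main__":
    main()
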
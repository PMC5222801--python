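"""Receptive-field adaptation with competitive weight normalization.

Same protocol as 02_rf_adaptation.py but with the subtractive normalization
rule conserving the summed weight.  Without training, DP/PP/UP narrow the
tuning curve and DU flattens it; with the training stimulus, DP/PP/UP retune
the receptive field to the trained input while DU silences it.  Untrained
runs use a long horizon (default 400 s); each trained rule is read out just
past its shift (PP 100 s, UP 200 s, DP/DU 400 s) — later, every boosted
input saturates at the bound and the peak degenerates to a tie.

Writes: results/rf_adaptation_normalized/... (same layout as 02)
"""

import argparse
import importlib.util
import sys
from pathlib import Path

from modplast.errors import ConfigurationError
from modplast.io import write_summary_json

_spec = importlib.util.spec_from_file_location(
    "rf_adaptation", Path(__file__).parent / "02_rf_adaptation.py"
)
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument(
        "--outdir", type=Path, default=Path("results/rf_adaptation_normalized")
    )
    ap.add_argument("--trials", type=int, default=100)
    ap.add_argument("--duration", type=float, default=400.0)
    args = ap.parse_args(argv)
    args.outdir.mkdir(parents=True, exist_ok=True)
    try:
        summary = _mod.run_block(
            args.outdir,
            args.seed,
            args.trials,
            args.duration,
            normalize=True,
            trained_durations={"PP": 100.0, "UP": 200.0},
        )
    except ConfigurationError as err:
        print(f"configuration error: {err}", file=sys.stderr)
        return 2
    summary["parameters"] = {
        "seed": args.seed,
        "n_trials": args.trials,
        "duration_s": args.duration,
        "normalization": "subtractive",
    }
    write_summary_json(summary, args.outdir / "summary.json")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
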
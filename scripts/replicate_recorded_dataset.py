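"""Optional: run the offline analysis on locally recorded sessions.

Not part of the automated checks.  Given one or more session directories in
the package's on-disk layout (``runNN.edf`` + ``markers.tsv``, e.g. a
download of a public motor-imagery dataset converted to this layout), this
script applies ASR, runs best-window cross-validation per phase, and prints
an accuracy table with the exact-binomial chance threshold and the group
mean with its type-A uncertainty.  Entirely offline.

Usage::

    python scripts/replicate_recorded_dataset.py SESSION_DIR [SESSION_DIR ...]
"""

import argparse
import json
from pathlib import Path

import numpy as np

from mibci import asr, windows
from mibci.evaluation import chance_interval, type_a_uncertainty
from mibci.io_epochs import epoch_trials, pool_phase, read_markers, read_recording


def analyse_session(session_dir: Path, seed: int = 0):
    markers = read_markers(session_dir / "markers.tsv")
    phases = {}
    run_phase = sorted({(run, ph) for _, _, run, ph in markers.events})
    for run, ph in run_phase:
        rec = read_recording(session_dir / f"run{run:02d}.edf",
                             run_id=run, phase=ph)
        baseline = asr.select_baseline(rec)
        calib = asr.calibrate_asr(baseline)
        rec = asr.apply_asr(rec, calib)
        phases.setdefault(ph, []).append(
            epoch_trials(rec, markers.for_run(run)))
    out = {}
    for ph, sets in sorted(phases.items()):
        eps = pool_phase(sets)
        best, score, _ = windows.best_window_analysis(eps, seed=seed)
        ci = chance_interval(eps.n_trials)
        out[ph] = {"n_trials": eps.n_trials, "best_window": best,
                   "accuracy_pct": score.mean_acc,
                   "threshold_pct": ci.threshold_pct}
    return out


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("sessions", nargs="+", type=Path)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=None)
    args = ap.parse_args()

    table = {}
    for sdir in args.sessions:
        table[sdir.name] = analyse_session(sdir, seed=args.seed)
        for ph, d in table[sdir.name].items():
            star = "*" if d["accuracy_pct"] > d["threshold_pct"] else " "
            print(f"{sdir.name} phase {ph}: {d['accuracy_pct']:5.1f}%{star} "
                  f"(n={d['n_trials']}, window {d['best_window'][0]:.2f}-"
                  f"{d['best_window'][0] + d['best_window'][1]:.2f} s, "
                  f"threshold {d['threshold_pct']}%)")

    for ph in sorted({p for s in table.values() for p in s}):
        accs = [s[ph]["accuracy_pct"] for s in table.values() if ph in s]
        if len(accs) >= 2:
            print(f"phase {ph} group mean {np.mean(accs):.1f}% "
                  f"± {type_a_uncertainty(accs):.1f}% (type A, n={len(accs)})")
    if args.out:
        args.out.write_text(json.dumps(
            {k: {str(p): d for p, d in v.items()} for k, v in table.items()},
            indent=1, default=list))


if __name__ == "__main__":
    main()
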
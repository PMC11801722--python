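"""Preprocess the reference session: spike densities, saccade detection
check, and the visual-responsiveness screen.

Reads results/session (run 01_simulate.py first); writes unit QC and a
saccade-detection summary under results/.
"""

from pathlib import Path

import numpy as np

from popsaliency import preprocess as pre
from popsaliency import synth

OUT = Path("results")


def main():
    session = synth.load_session(OUT / "session")
    rates, grid = pre.session_rates(session)
    qc = pre.unit_qc(session, rates, grid)
    qc.to_csv(OUT / "unit_qc.csv", index=False)
    print(
        f"{int(qc['visually_responsive'].sum())}/{len(qc)} units pass the "
        "visual-responsiveness screen (paired t, 40-120 vs -150-0 ms)"
    )

    # saccade detection vs the generator's plan: every trial has >= 1 saccade
    n_detected = []
    for i in range(session.n_trials):
        ev = pre.detect_saccades(
            session.eye_t, session.eye[i, :, 0], session.eye[i, :, 1]
        )
        n_detected.append(len(ev))
    n_detected = np.array(n_detected)
    print(
        f"saccade detector: {np.mean(n_detected >= 1):.1%} of trials with >= 1 "
        f"event (mean {n_detected.mean():.2f}/trial)"
    )
    np.savetxt(OUT / "saccades_per_trial.csv", n_detected, fmt="%d", header="n_saccades")


if __name__ == "__main__":
    main()
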
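"""Generate the reference synthetic session used by the downstream analyses.

100 units with the default archetype mix (35% suppression, 20% biphasic, 15%
enhancement, 30% nonselective), planted subspace overlap 0.5, 40 trials per
display x RF-content condition.  Writes the session directory and a short
summary under results/.
"""

from pathlib import Path

from popsaliency import synth

SEED = 1
OUT = Path("results")


def main():
    pop = synth.make_unit_population(
        100, geometry=synth.GeometrySpec(d_true=5, overlap=0.5), seed=SEED
    )
    session = synth.simulate_session(pop, n_trials_per_condition=40, seed=SEED + 1)
    synth.save_session(session, OUT / "session")
    counts = session.trials.groupby(["display_type", "rf_content"]).size()
    print(f"session: {session.n_units} units, {session.n_trials} trials")
    print(counts.to_string())
    angles = synth.planted_principal_angles_deg(pop)
    print(f"planted target/singleton principal angles (deg): {angles.round(1)}")
    (OUT / "session_summary.txt").write_text(
        f"{session.n_units} units, {session.n_trials} trials\n{counts.to_string()}\n"
        f"planted principal angles (deg): {angles.round(2).tolist()}\n"
    )


if __name__ == "__main__":
    main()
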
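from beliefvar.observer import SampleDraw, TrialRecord


def make_trials(draw_sets, reported, p_blue=0.5):
    """Build TrialRecords from [(B, R), ...] per-trial sample lists."""
    return [
        TrialRecord(
            draws=[SampleDraw(b, r) for b, r in draws],
            reported_estimate=rep,
            jar_p_blue=p_blue,
            trial_id=i,
        )
        for i, (draws, rep) in enumerate(zip(draw_sets, reported))
    ]


def random_trials(rng, n_trials=20, rho=2.0, sigma=0.1):
    """Simulated trials from a rho/sigma observer on random 9-marble draws."""
    from beliefvar import fitting
    from beliefvar.observer import ObserverSpec

    spec = ObserverSpec("bayes_rho_sigma", {"rho": rho, "sigma": sigma})
    trials = [
        TrialRecord(
            draws=[SampleDraw(int(b), int(9 - b)) for b in rng.integers(0, 10, 5)],
            jar_p_blue=0.5,
            trial_id=i,
        )
        for i in range(n_trials)
    ]
    reported = fitting.simulate_responses(spec, trials, rng)
    for t, r in zip(trials, reported):
        t.reported_estimate = float(r)
    return trials
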
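"""Benchmark speed predictors against video ground truth.

Calibrates per-gait models on a seeded training cohort, then scores the
calibrated model and both general Froude-based predictors on an
independent 50-trackway hold-out with known speeds.  Signed percent error
is 100 (predicted - measured) / measured; negative = underestimate.  The
decadal histogram mirrors how such error distributions are reported.
"""

from trackway import (
    SpeciesProfile,
    default_specs,
    fit_all_gaits,
    generate,
    generate_holdout,
    summarize_errors,
)
from trackway.pipeline import predict_records

specs = default_specs()
train = generate(specs, seed=20170422)
hold = generate_holdout(specs, seed=20170504)
models = fit_all_gaits(train)
measured = {r.id: r.u_measured for r in hold}

for name in ("species", "alexander", "thulborn-wade"):
    rows = predict_records(
        hold, name, profile=SpeciesProfile(), gait_models=models
    )
    s = summarize_errors(
        [(r.u_pred, measured[r.trackway_id]) for r in rows], name
    )
    print(
        f"{name:13s}: mean |err| = {s.mean_abs:5.1f}% (SD {s.sd:.1f}), "
        f"signed mean = {s.mean_signed:+5.1f}%, range "
        f"[{s.min:.0f}, {s.max:.0f}]%"
    )
    hist = "  ".join(f"[{int(e):+d},{int(e)+10:+d}): {c}" for e, c in s.bins if c)
    print(f"               bins: {hist}")
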
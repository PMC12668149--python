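"""Four-stage nested calibration on synthetic data with known ground truth.

Generates noiseless growth-curve, co-culture and serial-dilution data from
the shipped recovery fixture, runs the staged fits, and prints recovered
versus true values for every free kinetic parameter.
"""

from feastfamine.calibration import (
    FitConfig,
    ObservationMapping,
    calibrate_dilution,
    fit_auxotroph,
    fit_global,
    fit_monoculture,
)
from feastfamine.synth import (
    RECOVERY_FIXED,
    RECOVERY_FREE,
    gen_recovery_dataset,
)

data = gen_recovery_dataset()
theta = data["theta"]


def cfg(stage, **kw):
    return FitConfig(stage=stage, free_params=RECOVERY_FREE[stage],
                     fixed_values=RECOVERY_FIXED, seed=1, **kw)


mono_map = ObservationMapping(state0=data["mono_state0"])
co_map = ObservationMapping(state0=data["co_state0"])

r1 = fit_monoculture(data["growth"], cfg("monoculture", max_evals=2000), mono_map)
print(f"stage 1 (monoculture): loss = {r1.loss_value:.3g}")
r2 = fit_auxotroph(data["coculture"], r1, cfg("auxotroph", max_evals=2500), co_map)
print(f"stage 2 (auxotroph, mu21 forced 0): loss = {r2.loss_value:.3g}")
r3 = fit_global(data["coculture"], r2, cfg("global", max_evals=4000), co_map)
print(f"stage 3 (global): loss = {r3.loss_value:.3g}")
r4 = calibrate_dilution(data["dilution"], r3,
                        cfg("dilution", max_evals=800, n_samples=50),
                        data["co_state0"], dt_dilution=data["dilution_dt"])
print(f"stage 4 (dilution, Δt = {data['dilution_dt']:g} d): loss = {r4.loss_value:.3g}")

print("\nparameter   recovered      true    rel. error")
for name in RECOVERY_FREE["global"]:
    got, want = getattr(r4.params, name), getattr(theta, name)
    err = abs(got - want) / want if want else abs(got)
    print(f"{name:>9s}  {got:10.5f}  {want:8.3f}    {err:8.3%}")
print("\nLosses are log-scale SSE (stages 1-3) and frequency SSE (stage 4);")
print("zero loss on noiseless data means the stage reproduced its input exactly.")
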
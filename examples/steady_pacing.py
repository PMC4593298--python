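"""Pace the demonstration cell model to its 1 Hz steady state.

The model is paced with its default stimulus until the pace-to-pace change
of the full ODE state (Euclidean norm) drops below 1e-6, i.e. successive
paces repeat the same trajectory.  The printed biomarkers summarise the
steady-state action potential: APD90/APD50 are the durations at 90%/50%
repolarisation, dV/dt_max is the maximum upstroke velocity.
"""

from apblock import PacingProtocol, compute_biomarkers, get_model, pace_to_steady

model = get_model("sixcurrent_demo")
protocol = PacingProtocol.for_model(model, frequency=1.0)

result = pace_to_steady(model, model.default_parameters, protocol)
marks = compute_biomarkers(result.final_trace)

print(f"converged: {result.converged} after {result.paces_run} paces "
      f"(final pace-to-pace norm {result.final_norm:.2e})")
print(f"resting potential : {marks.rest_v:8.2f} mV")
print(f"peak voltage      : {marks.peak_v:8.2f} mV")
print(f"max upstroke      : {marks.dvdt_max:8.1f} mV/ms")
print(f"APD90             : {marks.apd90:8.2f} ms")
print(f"APD50             : {marks.apd50:8.2f} ms")
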
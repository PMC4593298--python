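"""Full safety-screen study: hERG blocker over a concentration sweep.

A pure hERG/IKr blocker (pIC50 = 6, i.e. IC50 = 1 µM) is swept over
0.1-100 µM at 1 Hz pacing.  Each concentration re-paces the model to
steady state with the correspondingly reduced IKr conductance.  ΔAPD90 is
the percent change in action potential duration relative to the drug-free
control: progressive prolongation is the classic QT-liability signature,
and at high block the cell fails to repolarise at all, which is reported
as a message instead of a number.  Results are also exported as CSV.
"""

from apblock import (
    ChannelBlockSpec,
    ChannelId,
    CompoundSpec,
    ConcentrationRange,
    export_csv,
    run_study,
)

compound = CompoundSpec("hERG blocker",
                        (ChannelBlockSpec(ChannelId.IKr, pic50=6.0),))
result = run_study("sixcurrent_demo", compound,
                   ConcentrationRange(low=0.1, high=100.0, count=5))

print(f"{'conc (µM)':>10} {'IKr left':>9} {'APD90 (ms)':>11} "
      f"{'ΔAPD90 (%)':>11}  messages")
for row in result.rows:
    apd = f"{row.biomarkers.apd90:.1f}" if row.biomarkers.apd90 else "—"
    delta = (f"{row.delta_apd90_pct:+.1f}"
             if row.delta_apd90_pct is not None else "—")
    msgs = "; ".join(m.code.value for m in row.messages)
    print(f"{row.conc:10.3f} {row.factors[ChannelId.IKr]:9.3f} "
          f"{apd:>11} {delta:>11}  {msgs}")

files = export_csv(result, "herg_sweep_output")
print(f"\nwrote {len(files)} files to herg_sweep_output/ "
      "(summary.csv, per-concentration traces, metadata.json)")
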
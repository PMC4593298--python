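"""Per-channel block factors from screening potencies.

A compound with a hERG (IKr) pIC50 of 6 (IC50 = 1 µM) and a weaker CaV1.2
(ICaL) IC50 of 10 µM is evaluated over a concentration range.  The printed
factors are the fraction of each current remaining: 1.0 means untouched,
0.5 means half the current is blocked.  At exactly 1 µM — the hERG IC50 —
half the hERG current remains.
"""

from apblock import ChannelBlockSpec, ChannelId, CompoundSpec, block_factors

compound = CompoundSpec(
    name="example compound",
    blocks=(
        ChannelBlockSpec(ChannelId.IKr, pic50=6.0),
        ChannelBlockSpec.from_ic50(ChannelId.ICaL, ic50=10.0),
    ),
)

print(f"{'conc (µM)':>10} {'IKr remaining':>14} {'ICaL remaining':>15} {'INa remaining':>14}")
for conc in (0.0, 0.1, 1.0, 10.0, 100.0):
    f = block_factors(compound, conc)
    print(f"{conc:10.1f} {f[ChannelId.IKr]:14.3f} "
          f"{f[ChannelId.ICaL]:15.3f} {f[ChannelId.INa]:14.3f}")

print("\nINa stays at 1.0 throughout: no IC50 was supplied for it, so no "
      "block is applied to that channel.")
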
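"""Concentration-response mathematics for multi-channel block.

A compound's action on each cardiac ion channel is summarised by a single
fitted IC50 (or pIC50) and an optional Hill coefficient.  The fraction of
current remaining at a free concentration ``C`` is

    f(C) = 1 / (1 + (C / IC50)**hill)

so ``f(IC50) = 0.5`` for every Hill coefficient, ``f(0) = 1`` and ``f`` is
strictly decreasing in ``C``.  Channels without a measured IC50 are left
unblocked (factor exactly 1).  Only antagonism is modelled: factors never
exceed 1.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "ChannelId",
    "ChannelBlockSpec",
    "CompoundSpec",
    "BlockFactors",
    "fraction_remaining",
    "pic50_to_ic50",
    "ic50_to_pic50",
    "block_factors",
]


class ChannelId(enum.Enum):
    """The six screenable cardiac currents."""

    IKr = "IKr"
    ICaL = "ICaL"
    INa = "INa"
    IKs = "IKs"
    IK1 = "IK1"
    Ito = "Ito"

    def __str__(self) -> str:  # render
        return self.value

    @classmethod
    def parse(cls, text: str) -> "ChannelId":
        """Parse a channel name, case-insensitively, accepting common synonyms.

        ``"herg"`` maps to IKr, ``"nav1.5"`` to INa, ``"cav1.2"`` to ICaL,
        and so on for the channel-protein names of the standard screening
        panel.
        """
        key = text.strip().lower().replace("_", "").replace("-", "").replace(" ", "")
        try:
            return _CHANNEL_SYNONYMS[key]
        except KeyError:
            raise ValueError(
                f"unknown channel {text!r}; expected one of "
                f"{[c.value for c in cls]} or a synonym such as 'hERG'"
            ) from None


_CHANNEL_SYNONYMS: dict[str, ChannelId] = {}
for _c in ChannelId:
    _CHANNEL_SYNONYMS[_c.value.lower()] = _c
_CHANNEL_SYNONYMS.update(
    {
        "herg": ChannelId.IKr,
        "kv11.1": ChannelId.IKr,
        "kcnh2": ChannelId.IKr,
        "nav1.5": ChannelId.INa,
        "scn5a": ChannelId.INa,
        "na": ChannelId.INa,
        "cav1.2": ChannelId.ICaL,
        "cacna1c": ChannelId.ICaL,
        "cal": ChannelId.ICaL,
        "ltype": ChannelId.ICaL,
        "kvlqt1": ChannelId.IKs,
        "kcnq1": ChannelId.IKs,
        "kv7.1": ChannelId.IKs,
        "minke": ChannelId.IKs,
        "kir2.1": ChannelId.IK1,
        "kcnj2": ChannelId.IK1,
        "kv4.3": ChannelId.Ito,
        "kcnd3": ChannelId.Ito,
        "itofast": ChannelId.Ito,
    }
)


def fraction_remaining(conc: float, ic50: float, hill: float = 1.0) -> float:
    """Fraction of current remaining at ``conc`` for a Hill block curve.

    Parameters
    ----------
    conc : float
        Free compound concentration, in µM. Must be >= 0.
    ic50 : float
        Half-maximal inhibitory concentration, in µM. Must be > 0.
    hill : float
        Hill coefficient (curve steepness). Must be > 0. Default 1.

    Returns
    -------
    float
        ``1 / (1 + (conc/ic50)**hill)``, in ``(0, 1]``.
    """
    if not math.isfinite(ic50) or ic50 <= 0:
        raise ValueError(f"ic50 must be a positive finite number, got {ic50!r}")
    if not math.isfinite(hill) or hill <= 0:
        raise ValueError(f"hill must be a positive finite number, got {hill!r}")
    if not math.isfinite(conc) or conc < 0:
        raise ValueError(f"conc must be a non-negative finite number, got {conc!r}")
    if conc == 0.0:
        return 1.0
    return 1.0 / (1.0 + (conc / ic50) ** hill)


def pic50_to_ic50(pic50: float) -> float:
    """Convert a pIC50 (-log10 of the molar IC50) to an IC50 in µM.

    Uses the standard pharmacology convention pIC50 = -log10(IC50 [M]),
    hence IC50[µM] = 10**(6 - pIC50): pIC50 of 6 is 1 µM.
    """
    if not math.isfinite(pic50):
        raise ValueError(f"pic50 must be finite, got {pic50!r}")
    return 10.0 ** (6.0 - pic50)


def ic50_to_pic50(ic50: float) -> float:
    """Convert an IC50 in µM to a pIC50. Inverse of :func:`pic50_to_ic50`."""
    if not math.isfinite(ic50) or ic50 <= 0:
        raise ValueError(f"ic50 must be a positive finite number, got {ic50!r}")
    return 6.0 - math.log10(ic50)


# Hill coefficients far above physiological one-to-one binding are almost
# certainly data-entry errors; the accepted range is (0, 10].
MAX_HILL = 10.0


@dataclass(frozen=True)
class ChannelBlockSpec:
    """Potency of a compound against one channel, stored canonically as pIC50."""

    channel: ChannelId
    pic50: float
    hill: float = 1.0

    def __post_init__(self) -> None:
        if not isinstance(self.channel, ChannelId):
            object.__setattr__(self, "channel", ChannelId.parse(str(self.channel)))
        if not math.isfinite(self.pic50):
            raise ValueError(f"pic50 must be finite, got {self.pic50!r}")
        if not math.isfinite(self.hill) or not 0 < self.hill <= MAX_HILL:
            raise ValueError(
                f"hill must lie in (0, {MAX_HILL}], got {self.hill!r} "
                f"for channel {self.channel}"
            )

    @classmethod
    def from_ic50(
        cls, channel: ChannelId | str, ic50: float, hill: float = 1.0
    ) -> "ChannelBlockSpec":
        """Build from an IC50 in µM; converted to pIC50 on construction."""
        return cls(channel=channel, pic50=ic50_to_pic50(ic50), hill=hill)

    @property
    def ic50(self) -> float:
        """IC50 in µM."""
        return pic50_to_ic50(self.pic50)

    def fraction_remaining(self, conc: float) -> float:
        return fraction_remaining(conc, self.ic50, self.hill)


@dataclass(frozen=True)
class CompoundSpec:
    """A named compound with at most one block curve per channel.

    ``blocks`` may be empty: a compound with no measured block leaves every
    channel untouched.
    """

    name: str = "compound"
    blocks: tuple[ChannelBlockSpec, ...] = ()

    def __post_init__(self) -> None:
        blocks = tuple(self.blocks)
        object.__setattr__(self, "blocks", blocks)
        seen: set[ChannelId] = set()
        for b in blocks:
            if not isinstance(b, ChannelBlockSpec):
                raise TypeError(f"blocks must contain ChannelBlockSpec, got {b!r}")
            if b.channel in seen:
                raise ValueError(f"duplicate block entry for channel {b.channel}")
            seen.add(b.channel)

    def block_for(self, channel: ChannelId) -> ChannelBlockSpec | None:
        for b in self.blocks:
            if b.channel is channel:
                return b
        return None


@dataclass(frozen=True)
class BlockFactors:
    """Fraction of each current remaining, defined for all six channels.

    Channels the compound does not touch carry exactly 1.0.
    """

    factors: Mapping[ChannelId, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        full = {c: 1.0 for c in ChannelId}
        for c, v in dict(self.factors).items():
            if not isinstance(c, ChannelId):
                c = ChannelId.parse(str(c))
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"block factor for {c} must be in [0, 1], got {v!r}")
            full[c] = float(v)
        object.__setattr__(self, "factors", full)

    def __getitem__(self, channel: ChannelId) -> float:
        return self.factors[channel]

    def items(self) -> Iterable[tuple[ChannelId, float]]:
        return self.factors.items()


def block_factors(compound: CompoundSpec, conc: float) -> BlockFactors:
    """Per-channel fraction-remaining for ``compound`` at ``conc`` µM.

    Channels without a block curve get a factor of exactly 1.0; at zero
    concentration every factor is exactly 1.0.
    """
    if not math.isfinite(conc) or conc < 0:
        raise ValueError(f"conc must be a non-negative finite number, got {conc!r}")
    out: dict[ChannelId, float] = {}
    for b in compound.blocks:
        out[b.channel] = b.fraction_remaining(conc)
    return BlockFactors(out)
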
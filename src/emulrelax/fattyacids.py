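"""Fatty-acid composition utility.

The package ships gas-chromatography fatty-acid profiles (percent by
composition) of the beef and pork fats used as emulsion oil phases, as
a small packaged fixture.  `summarize_fatty_acids` computes named group
sums — e.g. the saturated palmitic + stearic share that dominates how
the fat type influences water dynamics.

Profile totals need not reach 100: minor acids below the detection
limit are omitted by the assay (the pork profile sums to ~97.1), so
totals are validated against a wide [95, 101] band with a warning, not
an error.
"""

from __future__ import annotations

import decimal
import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "FattyAcidProfile",
    "load_profiles",
    "load_profile_table",
    "summarize_fatty_acids",
    "DEFAULT_GROUPS",
]

#: Standard groupings: the two dominant saturated acids and the two
#: dominant unsaturated acids.
DEFAULT_GROUPS = {
    "palmitic_stearic": frozenset({"C16:0", "C18:0"}),
    "oleic_linoleic": frozenset({"C18:1", "C18:2"}),
}

_TOTAL_BAND = (95.0, 101.0)


@dataclass(frozen=True)
class FattyAcidProfile:
    """Percent composition by fatty-acid code for one fat."""

    fat: str
    composition: dict  # code -> percent

    def __post_init__(self) -> None:
        for code, pct in self.composition.items():
            if pct < 0:
                raise ValueError(f"negative percentage for {code}: {pct}")
        total = self.total
        if not _TOTAL_BAND[0] <= total <= _TOTAL_BAND[1]:
            warnings.warn(
                f"profile total for {self.fat} is {total:.2f}%, outside "
                f"[{_TOTAL_BAND[0]}, {_TOTAL_BAND[1]}]; minor acids may be "
                "missing or the profile may be malformed.",
                UserWarning,
                stacklevel=2,
            )

    @property
    def total(self) -> float:
        return float(sum(self.composition.values()))


def load_profile_table() -> pd.DataFrame:
    """The packaged fatty-acid profile fixture as a DataFrame."""
    with resources.files("emulrelax.data").joinpath("fatty_acid_profiles.csv").open() as fh:
        return pd.read_csv(fh)


def load_profiles() -> dict[str, FattyAcidProfile]:
    """Packaged beef and pork profiles keyed by fat label."""
    df = load_profile_table()
    out = {}
    for fat in ("beef", "pork"):
        col = f"{fat}_percent"
        sub = df[["code", col]].dropna()
        out[fat] = FattyAcidProfile(
            fat=fat, composition=dict(zip(sub["code"], sub[col].astype(float)))
        )
    return out


def _round_half_up(value: float, decimals: int = 1) -> float:
    q = decimal.Decimal(1).scaleb(-decimals)
    return float(
        decimal.Decimal(repr(float(value))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


def summarize_fatty_acids(
    profile: FattyAcidProfile, groups: dict[str, frozenset] | None = None
) -> dict[str, float]:
    """Per-group percentage sums, rounded half-up to one decimal.

    Group members absent from the profile contribute 0 with a warning;
    an empty group is an error.
    """
    if groups is None:
        groups = DEFAULT_GROUPS
    out = {}
    for name, codes in groups.items():
        if not codes:
            raise ValueError(f"group {name!r} is empty")
        missing = sorted(set(codes) - set(profile.composition))
        if missing:
            warnings.warn(
                f"group {name!r}: codes {missing} absent from the {profile.fat} "
                "profile, treated as 0.",
                UserWarning,
                stacklevel=2,
            )
        out[name] = _round_half_up(
            sum(profile.composition.get(c, 0.0) for c in codes)
        )
    return out
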
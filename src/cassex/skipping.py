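"""Cassette-exon skipping prediction from flanking donor-site signals.

The discriminant is the +6 intronic nucleotide of the two donor sites that
flank the cassette exon: the donor of the upstream intron (used by both
isoforms) and the exon's own donor (used only on inclusion). Empirically the
+6 identities rank T > C >= A > G in donor strength. Skipping arises when
the upstream donor carries a strong-or-neutral +6 (T or C) while the exon's
own donor carries a weak one (A or G): the spliceosome then favours pairing
the upstream donor across the exon. The rule is class-based, not a raw
ordinal comparison — a T-vs-C pair (both strong/neutral) predicts
constitutive retention.

A secondary rule compares the two donors' PWMS values directly: skipping is
called when the upstream score exceeds the downstream score by more than a
threshold (an artifact calibration, default 2.0, not a literature constant).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .errors import InsufficientEvidenceError, InvalidBaseError
from .seqtools import normalize

PLUS6_STRENGTH = {"T": 3, "C": 2, "A": 1, "G": 0}

STRONG_OR_NEUTRAL = frozenset("TC")
WEAK = frozenset("AG")

CONSTITUTIVE = "constitutive_retention"
SKIPPING = "alternative_skipping"
LOST = "exon_lost"

DEFAULT_DELTA_THRESHOLD = 2.0


@dataclass
class DonorPair:
    """The +6 identities (and optionally PWMS) of a cassette exon's flanking donors.

    ``upstream_plus6`` belongs to the donor of the intron upstream of the
    exon; ``downstream_plus6`` to the exon's own donor. ``exon_present`` is
    an annotation fact (False = the exon is lost from the genome).
    """

    upstream_plus6: str
    downstream_plus6: str
    upstream_pwms: Optional[float] = None
    downstream_pwms: Optional[float] = None
    exon_present: bool = True

    def __post_init__(self) -> None:
        self.upstream_plus6 = normalize(self.upstream_plus6)
        self.downstream_plus6 = normalize(self.downstream_plus6)


@dataclass
class SkippingCall:
    call: str          # constitutive_retention | alternative_skipping | exon_lost
    rule: str          # plus6 | pwms_delta
    detail: str


def plus6_strength(base: str) -> int:
    """Ordinal donor strength of a +6 nucleotide: T=3 > C=2 >= A=1 > G=0."""
    b = normalize(base)
    if b not in PLUS6_STRENGTH:
        raise InvalidBaseError(f"+6 base must be one of A/C/G/T, got {base!r}")
    return PLUS6_STRENGTH[b]


def predict_from_plus6(pair: DonorPair) -> SkippingCall:
    """The +6 class rule.

    Skip iff upstream +6 is strong/neutral (T or C) AND downstream +6 is
    weak (A or G); otherwise constitutive retention. A lost exon trumps
    everything.
    """
    if not pair.exon_present:
        return SkippingCall(LOST, "plus6", "exon absent from annotation")
    up, down = pair.upstream_plus6, pair.downstream_plus6
    plus6_strength(up), plus6_strength(down)  # validate both
    if up in STRONG_OR_NEUTRAL and down in WEAK:
        call = SKIPPING
    else:
        call = CONSTITUTIVE
    return SkippingCall(call, "plus6", f"upstream +6{up} ({'strong/neutral' if up in STRONG_OR_NEUTRAL else 'weak'}), "
                                       f"downstream +6{down} ({'weak' if down in WEAK else 'strong/neutral'})")


def predict_from_pwms(pair: DonorPair, delta_threshold: float = DEFAULT_DELTA_THRESHOLD) -> SkippingCall:
    """Secondary rule: skip iff upstream PWMS - downstream PWMS > threshold."""
    if not pair.exon_present:
        return SkippingCall(LOST, "pwms_delta", "exon absent from annotation")
    if pair.upstream_pwms is None or pair.downstream_pwms is None:
        raise InsufficientEvidenceError("both PWMS values are required for the pwms_delta rule")
    delta = pair.upstream_pwms - pair.downstream_pwms
    call = SKIPPING if delta > delta_threshold else CONSTITUTIVE
    return SkippingCall(call, "pwms_delta", f"delta = {delta:.4f} vs threshold {delta_threshold:g}")


def classify_panel(
    rows: Sequence[tuple[str, str, DonorPair]],
    rule: str = "plus6",
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify a (species, group, DonorPair) panel.

    Returns (per-row calls, per-group tallies of each call class).
    """
    out = []
    for species, group, pair in rows:
        if rule == "plus6":
            call = predict_from_plus6(pair)
        elif rule == "pwms_delta":
            call = predict_from_pwms(pair, delta_threshold)
        else:
            raise InvalidBaseError(f"unknown rule {rule!r}")
        out.append(dict(
            species=species, group=group,
            upstream_plus6=pair.upstream_plus6, downstream_plus6=pair.downstream_plus6,
            upstream_pwms=pair.upstream_pwms, downstream_pwms=pair.downstream_pwms,
            call=call.call, rule=call.rule, detail=call.detail,
        ))
    calls = pd.DataFrame(out, columns=["species", "group", "upstream_plus6", "downstream_plus6",
                                       "upstream_pwms", "downstream_pwms", "call", "rule", "detail"])
    if calls.empty:
        summary = pd.DataFrame(columns=["group", CONSTITUTIVE, SKIPPING, LOST])
    else:
        summary = (
            calls.groupby("group")["call"].value_counts().unstack(fill_value=0)
            .reindex(columns=[CONSTITUTIVE, SKIPPING, LOST], fill_value=0)
            .reset_index()
        )
    return calls, summary


def pair_from_donor_13mers(
    upstream: str, downstream: str, exon_present: bool = True,
    pwm=None,
) -> DonorPair:
    """Build a DonorPair from two 13-nt donor windows (5 exonic + 8 intronic).

    The +6 site is the sixth intronic base, i.e. position 10 (0-based) of
    the window. When a PWM is supplied the two PWMS values are scored on
    the fly.
    """
    up = normalize(upstream)
    down = normalize(downstream)
    if len(up) != 13 or len(down) != 13:
        raise InvalidBaseError("donor windows must be 13 nt (5 exonic + 8 intronic)")
    up_pwms = down_pwms = None
    if pwm is not None:
        from .pwm import score_sequence
        up_pwms = score_sequence(pwm, up).score
        down_pwms = score_sequence(pwm, down).score
    return DonorPair(
        upstream_plus6=up[10], downstream_plus6=down[10],
        upstream_pwms=up_pwms, downstream_pwms=down_pwms, exon_present=exon_present,
    )
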
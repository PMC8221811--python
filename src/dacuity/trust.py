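"""Investor-trustee exchange metrics.

Each round of the 10-round trust game is summarized by the fractional change
in what each party contributed, relative to what they *could* have
contributed: the investor out of their endowment, the trustee out of the
multiplied investment they held. The per-round (dI, dT) vectors are
classified into four strategy quadrants (retaliating, repairing, honoring,
disrupting), and their vector sum characterizes the whole exchange: its
orientation identifies the style of the game (coaxing exchanges sit near
0 deg, mutual-reduction exchanges near -135 deg), its length the overall
responsiveness, and the position of the orientation along the chord between
those two poles gives a cooperativeness score in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

CLASS_LABELS = ("retaliating", "repairing", "honoring", "disrupting")

#: Poles of the bimodal orientation distribution: mutual-reduction exchanges
#: (cooperativeness 0) sit at -135 deg = -3*pi/4, coaxing exchanges
#: (cooperativeness 1) at 0 deg.
ORIENT_LOW_DEG = -135.0
ORIENT_HIGH_DEG = 0.0


@dataclass
class TrustExchange:
    """One subject's multi-round exchange record."""

    endowment: np.ndarray  # per-round investor endowment (units)
    investor: np.ndarray   # per-round investor contribution
    trustee: np.ndarray    # per-round trustee return
    multiplier: float = 3.0

    def __post_init__(self):
        self.endowment = np.atleast_1d(np.asarray(self.endowment, float))
        self.investor = np.asarray(self.investor, float)
        self.trustee = np.asarray(self.trustee, float)
        n = self.investor.size
        if n < 2:
            raise ValueError("an exchange needs at least 2 rounds")
        if self.endowment.size == 1:
            self.endowment = np.full(n, self.endowment[0])
        if self.endowment.size != n or self.trustee.size != n:
            raise ValueError("endowment, investor and trustee must share round count")
        if np.any(self.investor < -1e-9) or np.any(self.investor > self.endowment + 1e-9):
            raise ValueError("contributions must lie in [0, endowment]")
        held = self.multiplier * self.investor
        if np.any(self.trustee < -1e-9) or np.any(self.trustee > held + 1e-9):
            raise ValueError("returns must lie in [0, multiplier * contribution]")

    @property
    def n_rounds(self) -> int:
        return self.investor.size


def _trustee_fraction(exchange: TrustExchange) -> np.ndarray:
    """Fraction of the multiplied investment the trustee gave back.

    A round where the investor gave nothing leaves the trustee with nothing
    to return; that fraction is defined as 0.
    """
    held = exchange.multiplier * exchange.investor
    zero = held <= 0
    if np.any(zero & (exchange.trustee > 0)):
        raise ValueError("invalid exchange: trustee returned money on a zero-investment round")
    frac = np.zeros_like(held)
    np.divide(exchange.trustee, held, out=frac, where=~zero)
    return frac


def classify_angle(angle_deg: float) -> str:
    """Quadrant class for a (dI, dT) vector by its angle from the dI axis.

    Quadrants are closed on the upper edge and labels run in the order
    retaliating, repairing, honoring, disrupting as the angle increases
    from -180 to 180 degrees.
    """
    if -180.0 < angle_deg <= -90.0 or math.isclose(angle_deg, -180.0):
        return "retaliating"
    if -90.0 < angle_deg <= 0.0:
        return "repairing"
    if 0.0 < angle_deg <= 90.0:
        return "honoring"
    return "disrupting"


def round_vectors(exchange: TrustExchange) -> list[tuple[float, float, Optional[str]]]:
    """Per-round fractional-change vectors (dI, dT) with quadrant class.

    For round t >= 2, dI is the change in the fraction of the endowment the
    investor contributed and dT the change in the fraction of available
    play-money the trustee returned. Exact zero vectors have no orientation
    and are left unclassified (class ``None``).
    """
    inv_frac = exchange.investor / exchange.endowment
    ret_frac = _trustee_fraction(exchange)
    out = []
    for t in range(1, exchange.n_rounds):
        di = float(inv_frac[t] - inv_frac[t - 1])
        dt = float(ret_frac[t] - ret_frac[t - 1])
        if di == 0.0 and dt == 0.0:
            out.append((di, dt, None))
        else:
            out.append((di, dt, classify_angle(math.degrees(math.atan2(dt, di)))))
    return out


def _chord_position(angle_deg: float) -> float:
    """Position in [0, 1] along the chord from the -135 deg pole to 0 deg."""
    u = np.array([math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))])
    a = np.array([math.cos(math.radians(ORIENT_LOW_DEG)), math.sin(math.radians(ORIENT_LOW_DEG))])
    b = np.array([math.cos(math.radians(ORIENT_HIGH_DEG)), math.sin(math.radians(ORIENT_HIGH_DEG))])
    t = (u - a) @ (b - a) / ((b - a) @ (b - a))
    return float(np.clip(t, 0.0, 1.0))


def exchange_scores(exchange: TrustExchange) -> dict[str, float]:
    """Whole-exchange scores: initial trust, orientation, responsiveness, cooperativeness.

    The resultant is the vector sum of the round vectors; its orientation
    characterizes the exchange as a whole. Responsiveness is the resultant
    length normalized by the number of round-to-round transitions.
    """
    vecs = round_vectors(exchange)
    res = np.array([0.0, 0.0])
    any_nonzero = False
    for di, dt, cls in vecs:
        res += (di, dt)
        any_nonzero = any_nonzero or cls is not None
    if not any_nonzero:
        raise ValueError("orientation undefined: every round vector is zero")
    orientation = math.degrees(math.atan2(res[1], res[0]))
    return {
        "initial_trust": float(exchange.investor[0] / exchange.endowment[0]),
        "orientation_deg": orientation,
        "responsiveness": float(np.hypot(*res) / (exchange.n_rounds - 1)),
        "cooperativeness": _chord_position(orientation),
    }


def score_exchanges(exchanges) -> pd.DataFrame:
    """Score a list of exchanges into a per-subject table."""
    rows = []
    for s, ex in enumerate(exchanges):
        scores = exchange_scores(ex)
        scores["subject"] = s
        rows.append(scores)
    return pd.DataFrame(rows)[
        ["subject", "initial_trust", "orientation_deg", "responsiveness", "cooperativeness"]
    ]


def read_exchanges_tsv(path, multiplier: float = 3.0) -> list[TrustExchange]:
    """Read exchange records from TSV with columns subject, round, endowment, investor, trustee."""
    df = pd.read_csv(path, sep="\t")
    required = {"subject", "round", "endowment", "investor", "trustee"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"exchange table missing columns: {sorted(missing)}")
    out = []
    for _, grp in df.sort_values(["subject", "round"]).groupby("subject"):
        out.append(
            TrustExchange(
                endowment=grp["endowment"].to_numpy(),
                investor=grp["investor"].to_numpy(),
                trustee=grp["trustee"].to_numpy(),
                multiplier=multiplier,
            )
        )
    return out


def write_exchanges_tsv(exchanges, path) -> None:
    rows = []
    for s, ex in enumerate(exchanges):
        for t in range(ex.n_rounds):
            rows.append(
                {
                    "subject": s,
                    "round": t + 1,
                    "endowment": ex.endowment[t],
                    "investor": ex.investor[t],
                    "trustee": ex.trustee[t],
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
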
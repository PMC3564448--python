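"""Lap schedule for the three-subtask figure-8 session.

A session interleaves three subtasks in fixed blocks:
VD (visually guided discrimination), SA (non-delayed spatial alternation) and
DA (delayed spatial alternation), in the order
VD 20, SA 20, VD 10, DA 20, VD 20, SA 20, VD 10, DA 20 (150 laps).

A lap's *journey* is the ordered pair (origin side, destination side); the
origin is physically the previous lap's destination. VD admits all four
journeys (the cue side is drawn at random); SA and DA admit only the crossing
journeys R-L and L-R, alternating on correct performance. Journey x subtask
yields eight trial types: VD1-VD4, SA1, SA2, DA1, DA2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import LEFT, RIGHT

SUBTASKS = ("VD", "SA", "DA")

#: the four ordered (origin, destination) journeys
JOURNEYS = ((RIGHT, LEFT), (LEFT, LEFT), (LEFT, RIGHT), (RIGHT, RIGHT))

#: canonical block structure: (subtask, n_laps)
DEFAULT_BLOCKS = (
    ("VD", 20), ("SA", 20), ("VD", 10), ("DA", 20),
    ("VD", 20), ("SA", 20), ("VD", 10), ("DA", 20),
)


@dataclass(frozen=True)
class TrialType:
    id: str
    subtask: str
    journey: tuple  # (origin, destination)


#: the eight trial types; VD1/SA1/DA1 share the R-L journey, VD3/SA2/DA2 the L-R
TRIAL_TYPES = {
    "VD1": TrialType("VD1", "VD", (RIGHT, LEFT)),
    "VD2": TrialType("VD2", "VD", (LEFT, LEFT)),
    "VD3": TrialType("VD3", "VD", (LEFT, RIGHT)),
    "VD4": TrialType("VD4", "VD", (RIGHT, RIGHT)),
    "SA1": TrialType("SA1", "SA", (RIGHT, LEFT)),
    "SA2": TrialType("SA2", "SA", (LEFT, RIGHT)),
    "DA1": TrialType("DA1", "DA", (RIGHT, LEFT)),
    "DA2": TrialType("DA2", "DA", (LEFT, RIGHT)),
}

_BY_KEY = {(tt.subtask, tt.journey): tt.id for tt in TRIAL_TYPES.values()}


def trial_type_of(subtask: str, journey: tuple):
    """Trial-type id for a (subtask, journey) pair, or None (error laps may
    produce same-side journeys in SA/DA, which are not one of the eight)."""
    return _BY_KEY.get((subtask, tuple(journey)))


@dataclass
class Lap:
    lap_index: int
    subtask: str
    cue_state: str  # 'left' | 'right' | 'both'
    journey: tuple  # actual (origin, destination) taken
    correct: bool
    delay: bool

    @property
    def trial_type(self):
        return trial_type_of(self.subtask, self.journey)


@dataclass
class LapSchedule:
    laps: list = field(default_factory=list)

    def __len__(self):
        return len(self.laps)

    def __iter__(self):
        return iter(self.laps)

    def __getitem__(self, i):
        return self.laps[i]

    def validate(self, blocks=DEFAULT_BLOCKS):
        sizes = [n for _, n in blocks]
        if [len(b) for b in self.blocks()] != sizes:
            raise ValueError("block lengths do not match the configured structure")
        prev_alt = None
        clean_since_alt = True  # no error lap since the last SA/DA lap
        for lap in self.laps:
            if lap.delay != (lap.subtask == "DA"):
                raise ValueError("delay flag must mark exactly the DA laps")
            if (lap.cue_state == "both") != (lap.subtask in ("SA", "DA")):
                raise ValueError("cue_state 'both' must mark exactly SA/DA laps")
            if lap.subtask in ("SA", "DA"):
                if lap.correct:
                    if lap.journey[0] == lap.journey[1]:
                        raise ValueError("correct SA/DA laps must cross sides")
                    if (prev_alt is not None and prev_alt.correct
                            and clean_since_alt and lap.journey == prev_alt.journey):
                        raise ValueError("correct SA/DA journeys must alternate")
                prev_alt = lap
                clean_since_alt = lap.correct
            elif not lap.correct:
                clean_since_alt = False
        return self

    def blocks(self):
        """Laps grouped into contiguous same-subtask blocks."""
        out, cur = [], []
        for lap in self.laps:
            if cur and lap.subtask != cur[-1].subtask:
                out.append(cur)
                cur = []
            cur.append(lap)
        if cur:
            out.append(cur)
        return out

    def correct_laps(self):
        return [lap for lap in self.laps if lap.correct]


def generate_schedule(blocks=DEFAULT_BLOCKS, error_rate: float = 0.0,
                      seed=0) -> LapSchedule:
    """Generate a lap schedule under a fixed seed.

    VD cue sides are uniform random; SA/DA laps alternate sides. Error laps
    (probability ``error_rate``) take the wrong side and are flagged
    ``correct=False``. To keep correct SA/DA laps alternating across the VD
    blocks that separate them, the final VD lap of a block preceding an SA/DA
    block has its cue forced to the side that continues the alternation.
    """
    if not (0.0 <= error_rate <= 1.0):
        raise ValueError("error_rate must lie in [0, 1]")
    for subtask, n in blocks:
        if subtask not in SUBTASKS or n <= 0:
            raise ValueError(f"invalid block {(subtask, n)}")
    rng = np.random.default_rng(seed)

    laps = []
    side = RIGHT if rng.random() < 0.5 else LEFT  # rat's starting side
    last_alt_dest = None  # destination of the most recent SA/DA lap
    idx = 0
    for b, (subtask, n) in enumerate(blocks):
        next_is_alt = b + 1 < len(blocks) and blocks[b + 1][0] in ("SA", "DA")
        for k in range(n):
            origin = side
            if subtask == "VD":
                if k == n - 1 and next_is_alt and last_alt_dest is not None:
                    cue = last_alt_dest  # keep cross-block alternation intact
                else:
                    cue = LEFT if rng.random() < 0.5 else RIGHT
                cue_state = "left" if cue == LEFT else "right"
                target = cue
            else:
                cue_state = "both"
                target = LEFT if origin == RIGHT else RIGHT  # cross to alternate
            err = rng.random() < error_rate
            dest = (LEFT if target == RIGHT else RIGHT) if err else target
            laps.append(Lap(idx, subtask, cue_state, (origin, dest),
                            correct=not err, delay=subtask == "DA"))
            if subtask in ("SA", "DA"):
                last_alt_dest = dest
            side = dest
            idx += 1
    return LapSchedule(laps).validate(blocks)
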
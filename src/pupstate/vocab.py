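"""Behaviour vocabulary and packaged defaults.

The scored ethogram for the pup-directed behaviour assay, the per-behaviour
peri-event analysis windows, and the default oestrous-stage switching table
live here so that every module shares one configuration surface.
"""

from __future__ import annotations

# -- scored behaviours -------------------------------------------------------

AGGRESSIVE_CONTACT = "aggressive_contact"
PUP_SNIFFING = "pup_sniffing"
PUP_GROOMING = "pup_grooming"
PUP_RETRIEVAL = "pup_retrieval"
CROUCHING = "crouching"
IN_NEST = "in_nest"
NEST_BUILDING = "nest_building"
REARING = "rearing"
DIGGING = "digging"
MALE_INTRUDER_SNIFFING = "male_intruder_sniffing"
FEMALE_INTRUDER_SNIFFING = "female_intruder_sniffing"

#: every label the assay scorer may emit
VOCABULARY = frozenset(
    {
        AGGRESSIVE_CONTACT,
        PUP_SNIFFING,
        PUP_GROOMING,
        PUP_RETRIEVAL,
        CROUCHING,
        IN_NEST,
        NEST_BUILDING,
        REARING,
        DIGGING,
        MALE_INTRUDER_SNIFFING,
        FEMALE_INTRUDER_SNIFFING,
    }
)

#: behaviours directed at pups; the earliest of these defines contact latency
PUP_DIRECTED = frozenset(
    {AGGRESSIVE_CONTACT, PUP_SNIFFING, PUP_GROOMING, PUP_RETRIEVAL, CROUCHING, IN_NEST}
)

#: any one of these after the initial investigation phase marks a parental animal
PARENTAL_DEFINING = frozenset({PUP_RETRIEVAL, CROUCHING, IN_NEST})

#: summed to give total parenting time
PARENTING_TIME_COMPONENTS = frozenset({PUP_GROOMING, PUP_RETRIEVAL, IN_NEST})

#: chemoinvestigation labels: first-bout selection requires a clean baseline
CHEMOINVESTIGATION = frozenset(
    {PUP_SNIFFING, MALE_INTRUDER_SNIFFING, FEMALE_INTRUDER_SNIFFING}
)

#: behaviours whose first bout is kept even with a contaminated baseline
BASELINE_EXEMPT = frozenset({PUP_GROOMING, AGGRESSIVE_CONTACT})

# -- peri-event analysis windows (half-window, seconds) ----------------------

DEFAULT_WINDOWS_S: dict[str, float] = {
    PUP_SNIFFING: 2.0,
    AGGRESSIVE_CONTACT: 2.0,
    PUP_GROOMING: 4.0,
    MALE_INTRUDER_SNIFFING: 5.0,
    FEMALE_INTRUDER_SNIFFING: 3.0,
}

# -- oestrous stages ---------------------------------------------------------

STAGES = ("P", "O", "M", "D")  # prooestrus, oestrus, metestrus, diestrus

# Stage-wise switching (aggression) probabilities. Metestrus and oestrus are
# the published anchor rates; prooestrus and diestrus are package defaults
# chosen so the frequency-weighted mean matches the ~60% overall switching
# rate after prolonged food deprivation.
DEFAULT_STAGE_PROBS: dict[str, float] = {"P": 0.62, "O": 0.32, "M": 0.70, "D": 0.62}

#: stage frequencies, proportional to the reference cohort sizes (30, 19, 40, 37)
DEFAULT_STAGE_FREQS: dict[str, float] = {
    "P": 30 / 126,
    "O": 19 / 126,
    "M": 40 / 126,
    "D": 37 / 126,
}

DEFAULT_ASSAY_DURATION_S = 15 * 60.0  #: pup interactions are recorded for 15 min
DEFAULT_FRAME_RATE_HZ = 20.0  #: imaging and per-channel photometry rate
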
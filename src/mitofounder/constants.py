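"""Reference-wide constants for the 16,569-bp circular mtDNA reference."""

#: Length of the circular reference in base pairs.
MT_LENGTH = 16569

#: Coding region, 1-based inclusive.  Positions outside this span (the
#: circular stretch CODING_END+1..MT_LENGTH plus 1..CODING_START-1) are the
#: control region / hyper-variable segments.
CODING_START = 577
CODING_END = 16023

#: Whole-molecule substitution rate (substitutions / site / year) used by
#: the ``complete_linear`` clock preset.
COMPLETE_RATE_PER_SITE_PER_YEAR = 1.691e-8

#: Default generation time in years.
GENERATION_TIME_YEARS = 25.0

#: Years per mutation implied by the complete-molecule linear clock:
#: 1 / (rate * length) ~ 3569 years.
YEARS_PER_MUTATION_COMPLETE = 1.0 / (COMPLETE_RATE_PER_SITE_PER_YEAR * MT_LENGTH)


def in_control_region(position: int) -> bool:
    """True if a 1-based position lies in the circular control-region span."""
    return position < CODING_START or position > CODING_END
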
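"""Unit conventions.

All user-facing times are minutes (dosing, sampling and simulation grids);
all rate parameters (clearances in L/h, hybrid rate constants in 1/h) live
on the hour scale internally.  Every conversion goes through this module so
the h<->min factor appears exactly once in the code base.
"""

MINUTES_PER_HOUR = 60.0


def minutes_to_hours(t_min):
    return t_min / MINUTES_PER_HOUR


def hours_to_minutes(t_h):
    return t_h * MINUTES_PER_HOUR
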
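"""Unit conversions used at module boundaries.

All internal math is SI (meters, seconds). AIS speeds arrive in knots,
grid geometry is usually quoted in kilometers; conversions happen once,
here, at ingest/report boundaries.
"""

KNOT_TO_MS: float = 0.514444
"""One international knot in meters per second."""

MS_TO_KNOT: float = 1.0 / KNOT_TO_MS

KM_TO_M: float = 1000.0
M_TO_KM: float = 1e-3
KM2_TO_M2: float = 1e6
M2_TO_KM2: float = 1e-6

HOUR_S: float = 3600.0
DAY_S: float = 86400.0


def knots_to_ms(v_kn: float) -> float:
    return v_kn * KNOT_TO_MS


def ms_to_knots(v_ms: float) -> float:
    return v_ms * MS_TO_KNOT
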
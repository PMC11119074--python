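from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, as tables in the clinical literature do.

    Python's built-in ``round`` uses banker's rounding (half to even), which
    would turn e.g. 32.505 into 32.50; published tables round 0.5 up.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
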
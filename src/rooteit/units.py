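"""Unit helpers.

All geometry inside the package is SI (meters). Instrument-facing quantities
keep their natural units (Hz, Ω, V, A, g). Inch-specified hardware dimensions
are converted at exactly 0.0254 m/in.
"""

INCH = 0.0254  # m per inch, exact


def inches(x: float) -> float:
    """Convert a length in inches to meters."""
    return x * INCH
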
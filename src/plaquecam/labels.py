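"""Class labels for the binary plaque-symptomatology task."""

ASY = "ASY"  # asymptomatic plaque
SY = "SY"    # symptomatic plaque

#: Fixed ordering of the probability vector returned by every scoring model.
CLASSES = (ASY, SY)


def class_index(label: str) -> int:
    """Position of ``label`` in the (ASY, SY) probability vector."""
    try:
        return CLASSES.index(label)
    except ValueError:
        raise ValueError(f"unknown class label {label!r}; expected one of {CLASSES}") from None
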
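"""Standard 12-lead montage: fixed order used everywhere in the package."""

LEAD_NAMES = ("DI", "DII", "DIII", "AVR", "AVL", "AVF",
              "V1", "V2", "V3", "V4", "V5", "V6")
LEAD_INDEX = {name: i for i, name in enumerate(LEAD_NAMES)}

ABNORMALITIES = ("1dAVb", "RBBB", "LBBB", "SB", "AF", "ST")


def lead_indices(names) -> list[int]:
    """Map lead names to indices in the fixed montage order, validating each."""
    out = []
    for name in names:
        if name not in LEAD_INDEX:
            raise ValueError(f"unknown lead name: {name!r}")
        out.append(LEAD_INDEX[name])
    return out
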
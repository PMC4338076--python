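"""Published assay outcomes of the GM/non-GM maize comparison study.

These are the *inputs* to the scoring rules in :mod:`allerscreen.serology`:
the band-by-time pepsin digestion (SGF) outcomes of the four seed
extracts, the per-serum immunoblot band assignments of the five maize
sensitized cases, and the qualitative GM ELISA absorbances, as read off
the study's gels and plates.  Encoding them here lets the desk-scale
worked examples (six SGF-stable fractions in non-GM maize, seven
IgE-binding fractions shared by all four extracts) be recomputed from
data rather than asserted.
"""

from __future__ import annotations

from .serology import BandMatrix, ImmunoblotTable

EXTRACTS = ("nonGM", "GM-Cry1Ab", "GM-Cry1Ac", "GM-Cry1C")

# presence codes per fraction over 0/1/5/15/30/45/60 min: p present, f faint,
# a absent.  Stable fractions persist as full bands through 60 min; "partially
# digested" fractions remain only as faint bands at 60 min; "digested within
# X min" fractions show a terminal faint band and are absent from X min on.
_SGF = {
    "nonGM": (
        [152, 120, 105, 90, 80, 60, 40, 38, 28, 19, 14, 10],
        {152: "ppppppf", 120: "ppppppf", 105: "ppppppf", 90: "ppppppf",
         80: "ppppppf", 40: "ppppppf",
         60: "ppppppp", 38: "ppppppp", 28: "ppppppp", 19: "ppppppp",
         14: "ppppppp", 10: "ppppppp"},
    ),
    "GM-Cry1Ac": (
        [175, 154, 126, 98, 80, 66, 58, 34, 22, 15, 9, 6],
        {175: "pppfaaa", 154: "pppfaaa", 126: "pppfaaa", 98: "pppfaaa",
         80: "pppfaaa", 22: "pppfaaa", 6: "pppfaaa",
         66: "ppppppp", 58: "ppppppp", 34: "ppppppp", 15: "ppppppp",
         9: "ppppppp"},
    ),
    "GM-Cry1Ab": (
        [170, 154, 133, 107, 97, 82, 68, 51, 36, 30, 25, 16, 7.7],
        {170: "pppppfa", 154: "pppppfa", 133: "pppppfa", 107: "pppppfa",
         97: "pppppfa", 82: "pppppfa", 51: "pppppfa", 7.7: "pppppfa",
         68: "ppppppp", 36: "ppppppp", 30: "ppppppp", 25: "ppppppp",
         16: "ppppppp"},
    ),
    "GM-Cry1C": (
        [160, 134, 118, 90, 77, 67, 59, 31, 28, 17, 14, 8.5],
        {160: "pppfaaa", 134: "pppfaaa", 118: "pppfaaa", 90: "pppfaaa",
         77: "pppfaaa", 59: "pppfaaa", 8.5: "pppfaaa",
         67: "ppppppp", 31: "ppppppp", 28: "ppppppp", 17: "ppppppp",
         14: "ppppppp"},
    ),
}

# IgE-reactive bands (kD) recognised per case; identical across the four
# extracts.  28 kD runs as a smear; 28/33/78 were each unique to one case,
# 41 and 48 were shared by two cases, and one case also bound 68 and 88.
IMMUNOBLOT_CASE_BANDS: dict[str, tuple[float, ...]] = {
    "case1": (28.0,),
    "case2": (41.0, 48.0),
    "case3": (78.0,),
    "case4": (33.0,),
    "case5": (41.0, 48.0, 68.0, 88.0),
}

# qualitative GM ELISA mean absorbances (sample, blank) at 450 nm
QUALITATIVE_ELISA_ODS = {
    "GM-Cry1Ab": (0.23, 0.07),
    "GM-Cry1Ac": (0.20, 0.07),
    "GM-Cry1C": (0.34, 0.07),
}

# specific-IgE category-count patterns (low / moderate / significant /
# very-high over 39 patient sera).  The published non-GM figures
# (16/15/9) sum to 40 over 39 sera; the consistent analogue 16/14/9 is
# used for synthetic reconstructions.
SIGE_CATEGORY_PATTERN: dict[str, tuple[int, int, int, int]] = {
    "nonGM": (16, 14, 9, 0),
    "GM-Cry1Ab": (19, 11, 9, 0),
    "GM-Cry1Ac": (16, 12, 11, 0),
    "GM-Cry1C": (21, 9, 9, 0),
}

N_PATIENTS = 39
N_CONTROLS = 11


def band_matrices() -> dict[str, BandMatrix]:
    """The four encoded SGF digestion matrices, keyed by extract."""
    out = {}
    for extract, (fractions, rows) in _SGF.items():
        out[extract] = BandMatrix.from_codes(
            extract,
            tuple(float(kd) for kd in fractions),
            [rows[kd] for kd in fractions],
        )
    return out


def immunoblot_tables() -> list[ImmunoblotTable]:
    """Per-(case, extract) immunoblot band tables for the five sera."""
    return [
        ImmunoblotTable(case_id=case, extract=extract, bands=bands)
        for extract in EXTRACTS
        for case, bands in IMMUNOBLOT_CASE_BANDS.items()
    ]
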
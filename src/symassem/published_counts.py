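"""The published clone-count dataset: 32 colony-by-year rows, adult and egg libraries.

Counts are transcribed exactly as printed (superscripts = retrieval tallies).
Sequences attached to these labels are synthetic placeholders generated by the
simulator — the percent similarity index depends only on counts, so PSI-based
checks are exact here, while distance-dependent statistics on this fixture are
non-canonical and flagged as such wherever they are reported.

Of the 29 observed labels, 24 are clade C and 5 clade D; 9 match previously
published types (C3, C17, C21, C21.6, C21.11, C31, C31.1, D1, D1a). C32.1 and
C32.2 carry the abnormal-fold pseudogene flag and are excluded by screening.
"""

from __future__ import annotations

PUBLISHED = {"C3", "C17", "C21", "C21.6", "C21.11", "C31", "C31.1", "D1", "D1a"}
PSEUDOGENES = {"C32.1", "C32.2"}

# (site, year, colony, adult counts, egg counts, printed PSI)
PUBLISHED_ROWS: list[tuple[str, int, str, str, str, float]] = [
    ("BTN", 2007, "1", "C31:5,C31.2:2,C21:2,C17:1", "C32.2:8,C31:1", 0.50),
    ("BTN", 2007, "8", "D1:4,D1a:4,D1a.1:2",
     "D1a:2,C31:2,C31.4:1,C21.2:1,C21.10:1,C17.2:1,C3:1", 0.22),
    ("BTN", 2007, "10", "D1a:4,D1:3,D1a.1:2", "C32.1:6,C31:2,C17.2:1", 0.00),
    ("BTN", 2007, "11", "D1a:7,D1:1,D1a.1:1", "D1a:5,D1a.1:3,D1:2", 0.72),
    ("BTN", 2007, "12", "D1:9,D1a:4",
     "C31:4,C17.2:2,D1a:1,C21:1,C31.1:1,C31.4:1,C32.1:1", 0.10),
    ("BTN", 2007, "18", "D1:3,D1a:3,D1a.1:2,D1a.2:1", "C31:9,C21:1,C17.2:1", 0.00),
    ("BTN", 2007, "19", "C31:3,C21:3,D1a:3,D1:1,D1a.1:1",
     "C31:5,C21.11:2,D1a:1,C17.2:1", 0.38),
    ("BTN", 2008, "8", "D1:5,D1a:4",
     "C21:3,C31.1:2,D1a:1,C21.3:1,C21.8:1,C21.5:1", 0.11),
    ("BTN", 2008, "10", "D1:5,D1a:5,D1a.1:1", "D1:4,D1a.1:3,D1a:2,C21.11:1", 0.69),
    ("BTN", 2008, "19",
     "C21:2,C21.2:2,C21.1:1,C21.4:1,C21.7:1,C21.9:1,C21.11:1,C31:1",
     "C21:3,C21.5:1,C21.6:1,C21.8:1,C21.11:1,C17.1:1,C32.2:1,D1a:1", 0.30),
    ("GL", 2007, "23", "C17.2:5,C31:3,C17:1,C21.11:1,C3.1:1",
     "C17.2:3,C31:3,C17.1:1,C21:1,C32.2:1", 0.65),
    ("GL", 2007, "29", "C31:8,C21:1", "C31:5,C31.1:1,C31.2:1,C3.1:1", 0.63),
    ("GL", 2007, "30", "C21:4,C31:3,C17.2:2,C21.11:2",
     "C31:3,C17.2:3,C17:1,C21.3:1,C31.1:1,C31.3:1", 0.45),
    ("GL", 2007, "35", "D1a:6,D1:3,D1.3:1,D1a.1:1", "D1a:5,D1:4,D1.3:1", 0.86),
    ("GL", 2007, "36", "C31:5,C21:2,C17.1:1,C31.4:1,D1:1",
     "C31:7,C32.1:2,C31.1:1", 0.50),
    ("GL", 2007, "37", "C17.2:6,C21.1:2,C21:1,C21.10:1,C31.2:1",
     "C31:8,C17.2:1,C31.1:1", 0.10),
    ("GL", 2007, "39", "C31:6,C31.1:2,C17.1:1,C21:1,C31.3:1",
     "C31:6,C31.2:2,C31.1:1,C31.3:1,C3:1", 0.73),
    ("GL", 2008, "23", "C17.1:2,C31:2,C21:1,C21.4:1,C21.8:1",
     "C21:7,C17:1,C21.9:1,C31.2:1", 0.14),
    ("GL", 2008, "29", "C21:7,C31:2", "C21:9,C31:1", 0.88),
    ("GL", 2008, "37", "C21:5,C21.10:3,C21.2:1,C21.11:1,C31:1",
     "C31:3,C21:2,C21.8:2,C21.3:1,C21.5:1,C21.11:1", 0.38),
    ("PR", 2008, "B1", "C21:4,C21.6:2,C21.10:2,C21.11:2,C31.4:1",
     "C31:5,C21:2,C21.11:1,C3.1:1,D1:1,D1a.2:1", 0.27),
    ("PR", 2008, "B2", "C21:4,C31:4,C21.11:2,C17.2:1",
     "C17.2:4,C21:2,C21.4:1,C21.6:1,C21.7:1,C21.11:1,C31:1", 0.45),
    ("PR", 2008, "B5", "C21:3,C31:3,C21.7:2,C21.1:1,C21.11:1,C17.2:1",
     "C21:4,C31:3,C21.2:1,C21.11:1,C17.2:1,D1:1", 0.73),
    ("PR", 2008, "B6", "C21.9:3,C31:2,C21.4:2,C17.1:1,C21:1,C21.10:1",
     "C31:5,C17.2:3,C21.5:1,C17:1,C32.2:1", 0.20),
    ("PR", 2008, "B7", "C21:4,C31:3,C17.1:1,C17.2:1,C21.6:1,C21.11:1",
     "C31:3,C31.1:2,C31.2:2,D1.3:2,C21.11:1,C32.2:1", 0.36),
    ("PR", 2008, "B8", "C31:5,C21.8:2,C21:1,C21.1:1,C21.11:1,C31.1:1",
     "C21:6,C17.2:2,C31:2,C21.5:1,C21.9:1,C21.10:1", 0.24),
    ("PR", 2008, "P1", "C31:4,C21.1:2,C21.2:2,C17.1:1,C21:1,C21.11:1",
     "C21:4,C21.6:2,C31:2,C17.2:2,C21.5:1", 0.27),
    ("PR", 2008, "P2", "C31:3,C21:3,C21.11:3,C17.2:1,C21.4:1",
     "C31:3,C21:3,C17.2:1,C21.6:1,D1a:1", 0.64),
    ("PR", 2008, "P5", "C31:5,C3:1,C21:1,C21.7:1,C21.10:1,C21.11:1,C31.2:1",
     "D1a.1:5,D1:4,D1a:3,D1a.2:1", 0.00),
    ("PR", 2008, "P6", "C31:3,C21:3,C21.3:2,C21.11:2,C21.2:1",
     "C21:5,C31:3,C21.4:1,C21.11:1,C3:1", 0.64),
    ("PR", 2008, "P7", "D1a.1:7,D1a:3,C21:1,C21.8:1",
     "D1a:4,D1a.1:1,D1:1,C21:1,C21.8:1", 0.54),
    ("PR", 2008, "P9", "C21:6,C21.5:1,C21.8:1,C31:1,C17.2:1",
     "C21:4,C21.11:2,C21.2:1,C21.3:1,C21.8:1,C31:1,D1a.1:1", 0.55),
]

# site-dominant colony morphologies as sampled: branching at BTN, plating at
# GL; at PR the B-prefixed colonies were branching and P-prefixed plating
_PR_MORPHOLOGY = {"B": "branching", "P": "plating"}


def parse_counts(spec: str) -> dict[str, int]:
    out: dict[str, int] = {}
    for piece in spec.split(","):
        label, _, count = piece.partition(":")
        out[label.strip()] = int(count)
    return out


def morphology_for(site: str, colony: str) -> str:
    if site == "BTN":
        return "branching"
    if site == "GL":
        return "plating"
    return _PR_MORPHOLOGY.get(colony[:1], "unknown")


def all_labels() -> list[str]:
    labels: set[str] = set()
    for _, _, _, adult, egg, _ in PUBLISHED_ROWS:
        labels |= set(parse_counts(adult)) | set(parse_counts(egg))
    return sorted(labels)


def printed_psi() -> dict[tuple[str, int, str], float]:
    """Printed PSI column keyed by (site, year, colony)."""
    return {(site, year, colony): psi for site, year, colony, _, _, psi in PUBLISHED_ROWS}
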
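import random

import pytest

from hgt_evidence import signature_scan
from hgt_evidence.io_formats import SequenceRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture(scope="session")
def consensus():
    """The parsed PAP I signature consensus (11 positions)."""
    return signature_scan.parse_pattern(signature_scan.PAP_CONSENSUS)


@pytest.fixture
def rng():
    return random.Random(20210127)


def random_protein(rng, length):
    return SequenceRecord(
        id=f"p{rng.randrange(10**6)}",
        residues="".join(rng.choice(AA20) for _ in range(length)),
        alphabet="aa",
    )


def oracle_scan(residues, pattern_text, max_mismatches,
                hydrophobic=frozenset("AVLIMFWC")):
    """Independent window-by-window scanner used as the test oracle.

    Re-interprets the pattern grammar from scratch: bracketed sets, bare
    residues, x wildcard, h hydrophobic, hyphens ignored.
    """
    classes = []
    i = 0
    while i < len(pattern_text):
        ch = pattern_text[i]
        if ch == "-":
            i += 1
        elif ch == "x":
            classes.append(None)
            i += 1
        elif ch == "h":
            classes.append(set(hydrophobic))
            i += 1
        elif ch == "[":
            j = pattern_text.index("]", i)
            classes.append(set(pattern_text[i + 1:j]))
            i = j + 1
        else:
            classes.append({ch})
            i += 1
    hits = []
    for off in range(len(residues) - len(classes) + 1):
        window = residues[off:off + len(classes)]
        mm = sum(1 for k, res in enumerate(window)
                 if classes[k] is not None and res not in classes[k])
        if mm <= max_mismatches:
            hits.append((off + 1, window, mm))
    return hits
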
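"""Independent naive reference implementations used only by the tests.

These deliberately share no code with the package internals: candidate
enumeration by literal window scanning, and IUPAC matching via a local
expansion table.
"""

from typing import List, Tuple

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

IUPAC_TABLE = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}

PAM_TAILS = {"NGG": "GG", "NAG": "AG"}


def naive_revcomp(s: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(s))


def naive_iupac(pattern: str, s: str) -> bool:
    return all(c in IUPAC_TABLE[p] for p, c in zip(pattern, s))


def naive_enumerate(
    seq: str, pam_rule: str = "NGG", start_rule: str = "N"
) -> List[Tuple[int, int, str, str]]:
    """(start, stop, strand, site23) tuples by literal window scan."""
    tail = PAM_TAILS[pam_rule]
    out = []
    for i in range(len(seq) - 22):
        window = seq[i : i + 23]
        for strand, oriented in (("+", window), ("-", naive_revcomp(window))):
            if "N" in oriented:
                continue
            if oriented[21:23] != tail:
                continue
            if start_rule == "G" and oriented[0] != "G":
                continue
            out.append((i + 1, i + 23, strand, oriented))
    return out


def naive_site_scan(site23: str, enzymes) -> set:
    """{(enzyme, start, end, strand)} by per-position per-strand IUPAC scan,
    with palindromic same-interval double matches collapsed to '+'."""
    rc = naive_revcomp(site23)
    found = set()
    for enz in enzymes:
        m = len(enz.site)
        for i in range(len(site23) - m + 1):
            if naive_iupac(enz.site, site23[i : i + m]):
                found.add((enz.name, i + 1, i + m, "+"))
        for j in range(len(rc) - m + 1):
            if naive_iupac(enz.site, rc[j : j + m]):
                start, end = 23 - m + 1 - j, 23 - j
                if (enz.name, start, end, "+") not in found:
                    found.add((enz.name, start, end, "-"))
    return found
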
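"""In-silico PCR: predict products of the triplex assay on arbitrary templates.

An amplicon is formed whenever a forward primer anneals on one strand and a
reverse primer of the same family set anneals downstream on the other strand,
with the product length inside a configurable window (default 80-300 bp,
appropriate for a 300-cycle paired-end kit). Templates are scanned in both
orientations and every product is reported in the canonical plus orientation
of the product itself, i.e. with the forward primer at its 5' end.

Coordinates are 0-based half-open on the plus strand of the stored template.
The ``insert`` is the primer-free interior - the region a primer-trimmed
sequencing read actually covers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

from .primers import BindingSite, PrimerSet, TriplexAssay, find_binding_sites, revcomp

#: Default product length window in bp (primer-inclusive).
DEFAULT_LENGTH_WINDOW: Tuple[int, int] = (80, 300)

#: Default IUPAC-aware mismatch tolerance per primer site.
DEFAULT_MAX_MM = 2


@dataclass(frozen=True)
class Amplicon:
    """One predicted PCR product.

    ``start``/``end`` span the product on the plus strand of the template
    (forward primer 5' end through the end of the reverse-primer site).
    ``sequence`` is always given in the product's own plus orientation
    (forward primer first), so products found on the template's minus strand
    read as their reverse complement relative to the stored template.
    """

    template_id: str
    start: int
    end: int
    sequence: str
    insert: str
    primer_pair: Tuple[str, str]
    family: str
    mismatches: int = 0

    def __len__(self) -> int:
        return self.end - self.start


def _scan_orientation(
    template: str,
    template_id: str,
    pset: PrimerSet,
    max_mm: int,
    length_window: Tuple[int, int],
) -> List[Tuple[int, int, str, str, str, str, int]]:
    """All (start, end, seq, insert, fname, rname, mm) products on one strand."""
    lo, hi = length_window
    out = []
    fwd_sites: list[BindingSite] = []
    for f in pset.forwards:
        fwd_sites += [
            s
            for s in find_binding_sites(template, f, max_mm, template_id=template_id)
            if s.strand == "plus"
        ]
    rev_sites: list[BindingSite] = []
    for r in pset.reverses:
        rev_sites += [
            s
            for s in find_binding_sites(template, r, max_mm, template_id=template_id)
            if s.strand == "minus"
        ]
    for fs in fwd_sites:
        for rs in rev_sites:
            if rs.start < fs.end:
                continue  # reverse site must lie strictly downstream
            length = rs.end - fs.start
            if lo <= length <= hi:
                out.append(
                    (
                        fs.start,
                        rs.end,
                        template[fs.start : rs.end],
                        template[fs.end : rs.start],
                        fs.primer_name,
                        rs.primer_name,
                        fs.mismatches + rs.mismatches,
                    )
                )
    return out


def predict_amplicons(
    template,
    assay: TriplexAssay,
    max_mm: int = DEFAULT_MAX_MM,
    length_window: Tuple[int, int] = DEFAULT_LENGTH_WINDOW,
) -> List[Amplicon]:
    """Predict all products of the triplex assay on one template.

    ``template`` is a BarcodeRecord or any object with ``accession`` and
    ``sequence`` attributes, or a plain (id, sequence) tuple, or a bare
    string. An empty list means the template is not amplifiable by the assay.
    Products are sorted by length, then start coordinate.
    """
    if isinstance(template, str):
        tid, seq = "", template
    elif isinstance(template, tuple):
        tid, seq = template
    else:
        tid, seq = template.accession, template.sequence
    seq = seq.upper()
    lo, hi = length_window
    if not lo < hi:
        raise ValueError(f"bad length window {length_window}")
    n = len(seq)
    rc = revcomp(seq)
    found: dict[tuple, Amplicon] = {}
    for pset in assay.sets:
        for strand, oriented in (("plus", seq), ("minus", rc)):
            for start, end, s, ins, fn, rn, mm in _scan_orientation(
                oriented, tid, pset, max_mm, length_window
            ):
                if strand == "minus":
                    start, end = n - end, n - start
                amp = Amplicon(
                    template_id=tid,
                    start=start,
                    end=end,
                    sequence=s,
                    insert=ins,
                    primer_pair=(fn, rn),
                    family=pset.family,
                    mismatches=mm,
                )
                # a palindromic site can surface from both scans; keep one
                found.setdefault((start, end, fn, rn, s), amp)
    return sorted(found.values(), key=lambda a: (len(a), a.start, a.primer_pair))


def digest_database(
    db,
    assay: TriplexAssay,
    max_mm: int = DEFAULT_MAX_MM,
    length_window: Tuple[int, int] = DEFAULT_LENGTH_WINDOW,
) -> Dict[str, List[Amplicon]]:
    """Run :func:`predict_amplicons` over every record of a BarcodeDB.

    Returns an accession-ordered mapping; an empty list marks a
    non-amplifiable record (e.g. an off-target species).
    """
    out: Dict[str, List[Amplicon]] = {}
    for acc in sorted(db.records):
        out[acc] = predict_amplicons(db.records[acc], assay, max_mm, length_window)
    return out
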
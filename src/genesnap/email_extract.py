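"""E-mail address extraction from publication text.

Addresses are captured with a conservative regular expression; the address
most likely belonging to a given author is then picked by searching the
candidate set for the author's surname (case-insensitive, diacritics and
hyphens stripped), restricted to publications from the last five years so
stale addresses are avoided.  When no surname-matching address survives the
recency filter, the author is flagged for manual lookup instead.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .corpus import Author, Publication

__all__ = ["EMAIL_PATTERN", "AddressCandidate", "AddressSearchResult",
           "extract_emails", "best_address", "normalize_surname"]

# local part: letters/digits/._%+-; domain: dotted labels, TLD ≥2 letters
EMAIL_PATTERN = re.compile(
    r"[A-Za-z0-9._%+-]+@[A-Za-z0-9-]+(?:\.[A-Za-z0-9-]+)*\.[A-Za-z]{2,}"
)


@dataclass(frozen=True)
class AddressCandidate:
    address: str
    source_pub: str
    pub_year: int
    surname_match: bool


@dataclass(frozen=True)
class AddressSearchResult:
    """Outcome of a per-author address search.

    ``needs_review`` mirrors the manual-inspection step of the original
    workflow: True when no confident automatic pick exists.
    """

    address: Optional[str]
    source_pub: Optional[str]
    needs_review: bool
    candidates: tuple[AddressCandidate, ...] = ()


def extract_emails(text: str) -> set[str]:
    """All e-mail addresses in *text*, lowercased and deduplicated."""
    return {m.group(0).lower() for m in EMAIL_PATTERN.finditer(text)}


def normalize_surname(surname: str) -> str:
    """Casefold, strip diacritics, drop hyphens/apostrophes/spaces."""
    decomposed = unicodedata.normalize("NFKD", surname)
    stripped = "".join(c for c in decomposed if not unicodedata.combining(c))
    return re.sub(r"[-'\s]", "", stripped).casefold()


def best_address(
    author: Author,
    pubs_with_text: Sequence[tuple[Publication, str]],
    reference_year: int,
    recency_years: int = 5,
) -> AddressSearchResult:
    """Pick the address most likely belonging to *author*.

    Only publications from the last *recency_years* years on which the
    author appears are searched.  Among extracted addresses, those
    containing the normalized surname anywhere in the address qualify;
    ties are resolved by most recent publication year, then lexicographic
    order of the address.
    """
    surname = normalize_surname(author.surname)
    floor = reference_year - recency_years
    candidates: list[AddressCandidate] = []
    for pub, text in pubs_with_text:
        if pub.year <= floor or author.author_id not in pub.author_ids:
            continue
        for address in sorted(extract_emails(text)):
            candidates.append(AddressCandidate(
                address=address,
                source_pub=pub.pub_id,
                pub_year=pub.year,
                surname_match=surname in normalize_surname(address) if surname else False,
            ))
    matches = [c for c in candidates if c.surname_match]
    if not matches:
        return AddressSearchResult(None, None, True, tuple(candidates))
    best = min(matches, key=lambda c: (-c.pub_year, c.address))
    return AddressSearchResult(best.address, best.source_pub, False, tuple(candidates))
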
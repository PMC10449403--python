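"""Frozen English stopword list.

The list is shipped with the repository (never fetched at runtime) so that
tokenization is fully reproducible.  It is a snapshot of a standard English
function-word list with one deliberate adjustment: spatial prepositions
("over", "under", "above", "below", ...) are retained as content words,
because in scene descriptions they encode spatial relations between
objects and therefore carry scene-relevant meaning.
"""

from __future__ import annotations

STOPWORDS: frozenset[str] = frozenset(
    """
    a an the and or but if because as until while
    of at by for with to from in on is are was were be been being
    am i me my myself we our ours ourselves you your yours yourself
    yourselves he him his himself she her hers herself it its itself
    they them their theirs themselves
    this that these those there here
    what which who whom when where why how
    all any both each few more most other some such
    no nor not only own same so than then too very
    s t can will just don should now
    do does did doing have has had having
    would could shall may might must
    again further once
    """.split()
)


def default_stopwords() -> frozenset[str]:
    """Return the frozen stopword list."""
    return STOPWORDS
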
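"""Default function-word stoplist for content-word extraction.

Verbal scenario descriptions are reduced to their content words before
word-vector composition.  There is no canonical function-word inventory, so
this fixed list (determiners, pronouns, prepositions, conjunctions,
auxiliaries, and a few high-frequency adverbs with no scenario content) is
shipped as a replaceable default: pass your own stoplist to
:func:`idiorsa.models.extract_content_words` to match a different tagging
scheme.
"""

DEFAULT_STOPLIST: frozenset[str] = frozenset(
    """
    a an the this that these those some any each every either neither no
    i me my mine myself we us our ours ourselves you your yours yourself
    yourselves he him his himself she her hers herself it its itself they
    them their theirs themselves who whom whose which what
    am is are was were be been being
    do does did doing done
    have has had having
    will would shall should can could may might must ought
    and or but nor so yet both whether
    if then else when while because although though since unless until
    as than that whereas
    at by for from in into of off on onto out over to under up with within
    without about above across after against along among around before
    behind below beneath beside between beyond down during near through
    toward towards upon
    not never also just only even still too very quite rather really
    there here where how why
    again once much many more most other another such own same
    """.split()
)
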
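"""Dictionary matching and explicit-mention rules on example texts.

The term dictionary is deliberately over-inclusive — "I fell in love" hits
just like "I fell down" — which is why a classifier sits behind it.  The
explicit rules are precise: "parkinson" as a substring, and "PD" only as a
standalone case-sensitive word (so "updated" never matches).
"""

from pdsocial import dictionary_flag, explicit_mention, load_dictionary

dictionary = load_dictionary()
print(f"dictionary: {len(dictionary.terms)} terms "
      f"({len(dictionary.exercise_terms())} tagged exercise)\n")

texts = [
    "My tremor was worse this morning",
    "I fell in love with this little café downtown",
    "updated my profile picture",
    "My PD meds changed again",
    "Parkinson's walk on Saturday",
]
for text in texts:
    hit, matches = dictionary_flag(text, dictionary)
    parkinson, pd_abbrev = explicit_mention(text)
    terms = ", ".join(t for t, _ in matches) or "-"
    print(f"{text!r}")
    print(f"  dictionary hit: {hit:d} ({terms}); "
          f"explicit parkinson={parkinson:d} PD={pd_abbrev:d}")
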
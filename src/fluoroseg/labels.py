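"""Fixed label vocabularies shared across the pipeline.

Five pixel color classes drive clustering and classification; inside the
tooth region white and yellow enamel collapse into a single healthy
"white_yellow" class for staging.  The integer codes double as the fixed
tie-break order (lower code wins ties everywhere).
"""

WHITE, YELLOW, OPAQUE, BROWN, BACKGROUND = range(5)
CLASS_NAMES = ("white", "yellow", "opaque", "brown", "background")
CLASS_CODES = {name: code for code, name in enumerate(CLASS_NAMES)}

TOOTH_CLASSES = (WHITE, YELLOW, OPAQUE, BROWN)

# three-class map used within the tooth region
WHITE_YELLOW, OPAQUE3, BROWN3, BACKGROUND3 = range(4)
CLASS3_NAMES = ("white_yellow", "opaque", "brown", "background")

# 5-class -> 3-class collapse
TO_THREE_CLASS = {
    WHITE: WHITE_YELLOW,
    YELLOW: WHITE_YELLOW,
    OPAQUE: OPAQUE3,
    BROWN: BROWN3,
    BACKGROUND: BACKGROUND3,
}

NORMAL, STAGE1, STAGE2, STAGE3 = range(4)
STAGE_NAMES = ("Normal", "Stage 1", "Stage 2", "Stage 3")
STAGE_CODES = {name: code for code, name in enumerate(STAGE_NAMES)}
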
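# Caption grammar: one sentence per descriptor axis, joined in order
# distribution -> density -> abnormal areas.  User-overridable via
# generate_caption(..., templates=...).
distribution:
  radial: >-
    The vessels radiate from the periphery to the center in a root-like
    pattern, gradually thinning toward the center.
  reticular: >-
    The vessels form a fine reticular mesh across the image, leaving the
    middle of the image free of vessels.
  mixed: >-
    The vessels show a mixed pattern of thick radial trunks and fine
    reticular branches.
density:
  sparse: >-
    Vessel density is low, with only a few vessels covering a small part of
    the image.
  moderate: >-
    Vessel density is moderate, with vessels covering a noticeable part of
    the image.
  dense: >-
    Vessel density is high, with vessels covering a large part of the image.
abnormal_area: >-
    An abnormal area is visible in the {region} region.
no_abnormal: >-
    No abnormal areas are visible.
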
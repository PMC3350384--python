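# Keyword families for bio-function pathway clustering.
#
# A pathway is assigned the first cluster (in `precedence` order) whose
# keyword family matches its bio-function terms; pathways matching no
# family fall into "other".  Matching is case-insensitive substring
# matching, except that keywords listed under `word_boundary` are matched
# at word boundaries to avoid hits inside longer words ("growth" must not
# fire on "outgrowths", "death" not on "breathless").
#
# cell_cycle, growth and death jointly form the "cancer related" cluster
# in composition reports.
clusters:
  cancer:
    - cancer
    - tumor
    - tumorigenesis
    - neoplasia
    - carcinoma
    - adenocarcinoma
    - lymphoma
    - sarcoma
  cell_cycle:
    - cell cycle
    - mitosis
    - mitotic
    - g2 phase
    - m phase
    - s phase
    - g2/m
    - cell division
    - check point
    - checkpoint
    - arresting
  growth:
    - survival
    - growth
    - proliferation
  death:
    - apoptosis
    - death
word_boundary:
  - growth
  - death
  - g2 phase
  - m phase
  - s phase
precedence:
  - cancer
  - cell_cycle
  - growth
  - death
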
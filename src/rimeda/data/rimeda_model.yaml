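model_id: rimeda-13
notes: >
  Thirteen-factor model of the re-identification risk of a released medical
  dataset, organised in four perspectives (data, knowledge, attacker,
  technical/organisational). Entity list, weight domains and the D1/TO2
  double-impact flags follow the published factor tables. The influence
  matrix shipped alongside is a synthetic reconstruction encoded from the
  published qualitative descriptions of the factor interrelationships; the
  original prototype workbook's cell values are not publicly available in
  machine-readable form, so numeric aggregates of this model are properties
  of the reconstruction, not of the original workbook.

perspectives:
  - id: D
    name: Data
    description: >
      Properties measurable on the dataset itself: record uniqueness,
      record similarity, and the presence of particularly vulnerable
      quasi-identifier combinations.
  - id: W
    name: Knowledge
    description: >
      External knowledge an adversary can bring to bear: linkable external
      data sources, background or contextual information, released
      metadata, and inference potential within the data.
  - id: A
    name: Attacker
    description: >
      The adversary side: motivation to attempt re-identification, skills,
      and available resources.
  - id: TO
    name: Technical/organisational
    description: >
      The environment of the release: organisational risk awareness,
      quality of the anonymisation methods applied, and data security.
      Strong implementation scores as a point deduction (-3).

entities:
  - id: D1
    name: Uniqueness
    perspective: D
    weight_domain: [0, 1, 2, 3]
    double: true
    rubric:
      - "Attribute: proportion of unique records in the total number of records."
      - "0 = no unique records; 3 = large share of records is unique."
    countermeasures:
      - Generalise quasi-identifier attributes (coarser categories, intervals).
      - Suppress rare attribute values or outlier records.
      - Randomise (perturb) values so records cease to be unique.
  - id: D2
    name: Similarity
    perspective: D
    weight_domain: [0, 1, 2, 3]
    rubric:
      - "Attribute: number of similar records."
      - "0 = records highly similar (protective); 3 = hardly any similar records."
    countermeasures:
      - Aggregate records into equivalence classes of indistinguishable rows.
  - id: D3
    name: Vulnerable quasi-identifier
    perspective: D
    weight_domain: [0, 1, 2, 3]
    rubric:
      - "Attribute: risky quasi-identifier combinations contained in the dataset"
      - "(e.g. length of stay, treating physician, diagnosis, admission date,"
      - "date of birth, sex, zip code)."
      - "0 = none included; 3 = several such attributes released jointly."
    countermeasures:
      - Remove or generalise the vulnerable quasi-identifier attributes.
      - Suppress the joint release of high-risk attribute combinations.
  - id: W1
    name: External data sources
    perspective: W
    weight_domain: [1, 2, 3]
    rubric:
      - "Attributes: type, suitability and availability of linkable external sources."
      - "1 = scarcely available/unsuitable; 3 = suitable sources readily available."
  - id: W2
    name: Background/contextual information
    perspective: W
    weight_domain: [1, 2, 3]
    rubric:
      - "Attributes: type, suitability and availability of contextual knowledge"
      - "about data subjects or the release setting."
  - id: W3
    name: Metadata
    perspective: W
    weight_domain: [0, 1, 2, 3]
    rubric:
      - "Attributes: type, suitability and availability of released metadata."
      - "0 = no metadata released; 3 = rich, linkable metadata released."
  - id: W4
    name: Data inference
    perspective: W
    weight_domain: [1, 2, 3]
    rubric:
      - "Attribute: potential to infer hidden attributes from released ones."
      - "1 = low inference potential; 3 = high inference potential."
  - id: A1
    name: Motivation
    perspective: A
    weight_domain: [1, 2, 3]
    rubric:
      - "Degree of adversary motivation: 1 = low; 3 = high."
  - id: A2
    name: Skills
    perspective: A
    weight_domain: [1, 2, 3]
    rubric:
      - "Degree of adversary skills: 1 = low; 3 = high."
  - id: A3
    name: Resources
    perspective: A
    weight_domain: [1, 2, 3]
    rubric:
      - "Degree of adversary resources (time, compute, funding): 1 = low; 3 = high."
  - id: TO1
    name: Awareness
    perspective: TO
    weight_domain: [-3, 1, 2, 3]
    rubric:
      - "Degree of implementation of organisational risk awareness."
      - "-3 = strongly implemented (risk-reducing); 1-3 = weakly implemented,"
      - "increasingly risk-driving."
    countermeasures:
      - Train staff and management on re-identification risk before release.
  - id: TO2
    name: Methods
    perspective: TO
    weight_domain: [-3, 1, 2, 3]
    double: true
    rubric:
      - "Type and quality of the anonymisation/pseudonymisation methods applied."
      - "-3 = high-quality methods applied (risk-reducing); 1-3 = weak or no"
      - "methods, increasingly risk-driving."
    countermeasures:
      - Apply state-of-the-art generalisation, suppression and randomisation.
      - Verify formal guarantees (e.g. k-anonymity) before release.
  - id: TO3
    name: Data security
    perspective: TO
    weight_domain: [-3, 1, 2, 3]
    rubric:
      - "Degree of implementation of technical data security measures."
      - "-3 = strongly implemented; 1-3 = weakly implemented."
    countermeasures:
      - Restrict access, encrypt in transit and at rest, log data use.

matrix:
  csv: influence_matrix_synthetic.csv

weighting_strategy: row
q_convention: active_sign

bands:
  mode: equal_width
  n_bands: 4
  labels: [low, moderate, high, critical]
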
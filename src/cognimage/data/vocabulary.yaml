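# Default attribute vocabulary for semantic-network knowledge bases.
#
# Each record defines an attribute name, its parameter arity (ordered kinds)
# and its category.  Parameter kinds:
#   node     - reference to another node in the network
#   scalar   - numeric value; mm / native units ("cm" suffix accepted)
#   vertices - variadic list of (feature_value, confidence) pairs
#   nodes    - variadic list of node references
#   word     - bare token (e.g. an optimizer name)
# A record with an empty params list is a flag attribute.
#
# Categories map one-to-one onto agent families:
#   segmentation-param / preprocessing -> segmentation agents
#   unary-feature / relational-feature / decision -> reasoning agents
#   learning -> knowledge agents (external-predictor training hooks)
#
# Users may extend this vocabulary with their own file.

attributes:
  # --- segmentation parameters ---------------------------------------
  - name: IntensityRange            # low, high in image intensity units (e.g. HU)
    category: segmentation-param
    params: [scalar, scalar]
  - name: MinSize                   # smallest candidate component, voxels
    category: segmentation-param
    params: [scalar]
  - name: ExternalPredictor         # delegate segmentation to a registered hook
    category: segmentation-param
    params: []
  - name: FillHoles                 # post-processing: topological hole filling
    category: segmentation-param
    params: []
  - name: MorphOpen                 # morphological opening, radius in mm
    category: segmentation-param
    params: [scalar]
  - name: MorphClose                # morphological closing, radius in mm
    category: segmentation-param
    params: [scalar]
  - name: BoxAbove                  # ref, in-plane width mm, height mm, offset low mm, offset high mm
    category: segmentation-param
    params: [node, scalar, scalar, scalar, scalar]
  - name: BoxBelow
    category: segmentation-param
    params: [node, scalar, scalar, scalar, scalar]
  - name: InferiorTipOf             # landmark: inferior-most point of the reference region
    category: segmentation-param
    params: [node]
  - name: SuperiorTipOf             # landmark: superior-most point of the reference region
    category: segmentation-param
    params: [node]
  - name: BifurcationOf             # landmark: point where the reference region first splits
    category: segmentation-param
    params: [node]
  - name: AcceptanceThreshold       # minimum aggregate score for candidate acceptance
    category: segmentation-param
    params: [scalar]

  # --- unary features --------------------------------------------------
  - name: XSectionAreaFuzzy         # mean per-slice cross-sectional area, cm^2
    category: unary-feature
    params: [vertices]
  - name: VolumeFuzzy               # region volume, mm^3 (area mm^2 in 2D)
    category: unary-feature
    params: [vertices]
  - name: MeanIntensityFuzzy        # mean image intensity over the region
    category: unary-feature
    params: [vertices]

  # --- relational features ---------------------------------------------
  - name: PartOf                    # physical composition; parent node
    category: relational-feature
    params: [node]
  - name: NotPartOf                 # spatial exclusion; scored as 1 - overlap
    category: relational-feature
    params: [node]
  - name: InsideOf                  # containment within the reference region
    category: relational-feature
    params: [node]
  - name: LeftOf                    # ref, expected lateral distance low mm, high mm
    category: relational-feature
    params: [node, scalar, scalar]
  - name: RightOf
    category: relational-feature
    params: [node, scalar, scalar]
  - name: Above                     # ref, expected vertical distance low mm, high mm
    category: relational-feature
    params: [node, scalar, scalar]
  - name: Below
    category: relational-feature
    params: [node, scalar, scalar]
  - name: SameLevelAs               # ref, vertical tolerance mm
    category: relational-feature
    params: [node, scalar]

  # --- decisions --------------------------------------------------------
  - name: DecisionInside            # tip/landmark node, zone node
    category: decision
    params: [node, node]
  - name: DecisionPathWithin        # path node, containing region node, containment fraction
    category: decision
    params: [node, node, scalar]
  - name: DecisionAnd               # conjunction of >= 2 decision nodes
    category: decision
    params: [nodes]
  - name: ConsistentWith            # estimate a, estimate b, tolerance mm
    category: decision
    params: [node, node, scalar]

  # --- preprocessing ----------------------------------------------------
  - name: NormChannels              # number of input channels (1-3)
    category: preprocessing
    params: [scalar]
  - name: NormMinMax                # channel index
    category: preprocessing
    params: [scalar]
  - name: NormCentileClip           # channel index, low centile, high centile
    category: preprocessing
    params: [scalar, scalar, scalar]
  - name: NormHistEq                # channel index
    category: preprocessing
    params: [scalar]
  - name: NormBiasField             # channel index; delegates to a registered hook
    category: preprocessing
    params: [scalar]
  - name: HistogramSource           # node whose region supplies normalization statistics
    category: preprocessing
    params: [node]

  # --- learning ---------------------------------------------------------
  - name: NeuralNet_LearningRate    # base, exponent: rate = base * 10^exponent
    category: learning
    params: [scalar, scalar]
  - name: NeuralNet_BatchSize
    category: learning
    params: [scalar]
  - name: NeuralNet_Optimizer
    category: learning
    params: [word]
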
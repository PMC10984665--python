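# Term lists for the parenchymal-liver-biopsy screen. A report mentioning a
# non-liver specimen is excluded even when "liver" or "hepatic" appears
# elsewhere; liver fine-needle aspirations and biopsies of hepatic tumors
# are excluded too. Precedence when several cues fire:
# non_liver_organ > tumor_biopsy > fine_needle_aspiration.
liver_terms:
  - liver
  - hepatic
non_liver_specimens:
  # specimen-line organ phrases: "<organ>, biopsy" style headers
  - "colon, biopsy"
  - "colon, polypectomy"
  - "stomach, biopsy"
  - "gastric, biopsy"
  - "duodenum, biopsy"
  - "esophagus, biopsy"
  - "skin, biopsy"
  - "breast, biopsy"
  - "breast, core biopsy"
  - "lung, biopsy"
  - "kidney, biopsy"
  - "pancreas, biopsy"
  - "gallbladder, cholecystectomy"
  - "gallbladder:"
  - "bone marrow, biopsy"
  - "lymph node, biopsy"
  - "omentum, biopsy"
fna_phrases:
  - "fine needle aspiration"
  - "fine-needle aspiration"
  - "fna"
  - "aspiration cytology"
tumor_phrases:
  - "hepatocellular carcinoma"
  - "cholangiocarcinoma"
  - "metastatic carcinoma"
  - "metastatic adenocarcinoma"
  - "liver, mass"
  - "liver mass, biopsy"
  - "hepatic mass"
  - "liver lesion, biopsy"
  - "tumor resection"
  - "hepatectomy for tumor"
  - "neoplasm, biopsy"
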
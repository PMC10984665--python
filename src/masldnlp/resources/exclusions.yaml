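# Coincident-disease lexicon: disease name -> surface forms. A disease is
# reported only when present-asserted (negated mentions are dropped).
hepatitis C:
  - hepatitis c
  - chronic hepatitis c
  - hcv
hepatitis B:
  - hepatitis b
  - chronic hepatitis b
  - hbv
autoimmune hepatitis:
  - autoimmune hepatitis
  - aih
primary biliary cholangitis:
  - primary biliary cholangitis
  - primary biliary cirrhosis
  - pbc
primary sclerosing cholangitis:
  - primary sclerosing cholangitis
  - psc
iron overload:
  - iron overload
  - hemochromatosis
  - haemochromatosis
  - hemosiderosis
alpha-1 antitrypsin deficiency:
  - alpha-1 antitrypsin deficiency
  - alpha 1 antitrypsin deficiency
  - a1at deficiency
Wilson disease:
  - wilson disease
  - wilson's disease
granuloma:
  - granuloma
  - granulomas
  - granulomatous inflammation
alcoholic hepatitis:
  - alcoholic hepatitis
  - alcoholic steatohepatitis
drug-induced liver injury:
  - drug-induced liver injury
  - drug induced liver injury
  - dili
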
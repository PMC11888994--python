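# Substring rules mapping free-text "reason for use" entries to indication
# categories.  First match wins; order therefore matters (e.g. "non-small cell
# lung" must be tried before any generic "lung" pattern, and nothing here may
# shadow another category's terms).  Matching is case-insensitive substring
# matching after whitespace normalisation.  A blank reason maps to "no_entry"
# and a non-matching one to "other" before these rules are consulted.
rules:
  - {pattern: "colorectal", category: colorectal}
  - {pattern: "colon cancer", category: colorectal}
  - {pattern: "rectal cancer", category: colorectal}
  - {pattern: "sigmoid colon", category: colorectal}
  - {pattern: "cecal cancer", category: colorectal}
  - {pattern: "non-small cell lung", category: nsclc}
  - {pattern: "non small cell lung", category: nsclc}
  - {pattern: "lung adenocarcinoma", category: nsclc}
  - {pattern: "neoplasm of lung", category: nsclc}
  - {pattern: "neoplasms of the lung", category: nsclc}
  - {pattern: "lung cancer", category: nsclc}
  - {pattern: "breast cancer", category: breast}
  - {pattern: "glioma", category: malignant_glioma}
  - {pattern: "glioblastoma", category: malignant_glioma}
  - {pattern: "astrocytoma", category: malignant_glioma}
  - {pattern: "ovarian", category: ovarian}
  - {pattern: "cervical cancer", category: cervical}
  - {pattern: "hepatocellular", category: hepatocellular}
  - {pattern: "hcc", category: hepatocellular}
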
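pt_name,pt_code
Abdominal abscess,10060921
Abdominal hernia perforation,10074442
Abdominal wall abscess,10000099
Abscess intestinal,10000285
Acquired tracheo-oesophageal fistula,10000582
Anal abscess,10048946
Anal fistula,10002156
Anal fistula infection,10051540
Anal fistula repair,10082792
Anastomotic ulcer perforation,10002248
Anovulvar fistula,10050362
Aortoenteric fistula,10081100
Aorto-oesophageal fistula,10066870
Appendiceal abscess,10049764
Appendicitis perforated,10003012
Arterioenteric fistula,10070296
Atrio-oesophageal fistula,10075253
Chemical peritonitis,10070419
Colon fistula repair,10052931
Colonic abscess,10073573
Colonic fistula,10009995
Diverticular fistula,10013536
Diverticular perforation,10061820
Diverticulitis intestinal perforated,10084304
Douglas' abscess,10049583
Duodenal perforation,10013832
Duodenal ulcer perforation,10013849
"Duodenal ulcer perforation, obstructive",10013850
Duodenal ulcer repair,10069807
Enterocolonic fistula,10056991
Enterocutaneous fistula,10051425
Enterovesical fistula,10062570
Fistula of small intestine,10065850
Focal peritonitis,10084697
Gastric fistula,10065713
Gastric fistula repair,10071259
Gastric perforation,10017815
Gastric ulcer perforation,10017835
"Gastric ulcer perforation, obstructive",10017836
Gastrointestinal anastomotic leak,10065879
Gastrointestinal fistula,10017877
Gastrointestinal fistula repair,10071258
Gastrointestinal perforation,10018001
Gastrointestinal ulcer perforation,10061975
Gastropleural fistula,10067091
Gastrosplenic fistula,10068792
Ileal perforation,10021305
Ileal ulcer perforation,10021310
Inguinal hernia perforation,10075254
Intestinal fistula,10022647
Intestinal fistula infection,10051095
Intestinal fistula repair,10052991
Intestinal perforation,10022694
Intestinal ulcer perforation,10061248
Jejunal perforation,10023174
Jejunal ulcer perforation,10023178
Large intestinal ulcer perforation,10052497
Large intestine perforation,10023804
Lower gastrointestinal perforation,10078414
Mesenteric abscess,10072408
Neonatal intestinal perforation,10074160
Oesophageal abscess,10082996
Oesophageal fistula,10065835
Oesophageal fistula repair,10058381
Oesophageal perforation,10030181
Oesophageal rupture,10052211
Oesophageal ulcer perforation,10052488
Oesophageal-pulmonary fistula,10083015
Oesophagobronchial fistula,10056992
Oesophagomediastinal fistula,10084038
Oesophagopleural fistula,10077873
Pancreatic fistula,10049192
Pancreatic fistula repair,10058384
Peptic ulcer perforation,10034354
"Peptic ulcer perforation, obstructive",10034358
Perforated peptic ulcer oversewing,10034397
Perforated ulcer,10062065
Perineal abscess,10052457
Perirectal abscess,10052814
Peritoneal abscess,10034649
Peritoneocutaneous fistula,10076607
Peritonitis,10034674
Peritonitis bacterial,10062070
Pneumoperitoneum,10048299
Pneumoretroperitoneum,10068676
Procedural intestinal perforation,10074065
Rectal abscess,10048947
Rectal fistula repair,10053267
Rectal perforation,10038073
Rectoprostatic fistula,10074430
Rectourethral fistula,10066892
Retroperitoneal abscess,10038975
Small intestinal perforation,10041103
Small intestinal ulcer perforation,10052498
Umbilical hernia perforation,10066993
Upper gastrointestinal perforation,10078413
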
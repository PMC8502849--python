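study_id,alpha,n,n_items,year,continent,version,admin_method,care_context,n_women,n_men,age_mean,age_sd,score_mean,score_sd
S01,0.795612,12500,13,2021,europe,validated,other,other,11103.0,1397.0,67.2,,,
S02,0.800614,297,13,2009,europe,validated,other,geriatric_residence,266.0,31.0,31.9,11.2,53.8,7.3
S03,0.769393,265,13,2016,europe,validated,other,other,221.0,44.0,58.6,11.2,54.4,
S04,0.806022,238,13,2007,asia,original,face_to_face,geriatric_residence,195.0,43.0,,8.2,47.6,7.7
S05,0.751825,213,13,2018,europe,free_translation,other,geriatric_residence,174.0,39.0,63.0,12.8,,
S06,0.83921,191,13,2009,europe,validated,other,other,159.0,32.0,,,,
S07,0.852384,171,13,2016,europe,original,other,geriatric_residence,147.0,24.0,,10.2,,
S08,0.82259,153,13,2016,europe,validated,other,geriatric_residence,131.0,22.0,42.7,12.0,,
S09,0.665588,138,13,2009,europe,validated,other,geriatric_residence,115.0,23.0,68.0,9.9,,
S10,0.870365,123,13,2013,asia,validated,other,other,107.0,16.0,31.2,9.9,,
S11,0.882667,111,13,2008,europe,validated,face_to_face,geriatric_residence,,,24.0,8.5,,
S12,0.811845,99,13,2021,americas,free_translation,other,geriatric_residence,85.0,14.0,36.1,7.9,,
S13,0.780472,89,13,2014,europe,validated,face_to_face,geriatric_residence,74.0,15.0,49.8,,,
S14,0.848983,80,13,2009,oceania,validated,face_to_face,geriatric_residence,,,33.7,,,
S15,0.786627,71,13,2019,europe,validated,other,geriatric_residence,61.0,10.0,54.9,,,
S16,0.830708,64,13,2018,europe,validated,face_to_face,geriatric_residence,53.0,11.0,51.1,,,
S17,0.752344,57,13,2010,oceania,validated,face_to_face,geriatric_residence,47.0,10.0,50.0,,,
S18,0.68561,51,13,2012,europe,validated,face_to_face,geriatric_residence,44.0,7.0,,10.4,,
S19,0.913436,46,13,2008,europe,validated,other,geriatric_residence,40.0,6.0,39.3,12.6,,
S20,0.722076,41,13,2015,europe,original,other,geriatric_residence,35.0,6.0,65.7,9.3,,
S21,0.819879,37,13,2015,europe,validated,other,other,31.0,6.0,39.6,,48.0,5.9
S22,0.84159,33,13,2007,asia,validated,other,geriatric_residence,28.0,5.0,60.3,12.3,,
S23,0.694237,30,13,2009,asia,validated,other,other,,,54.3,12.4,,
S24,0.877634,27,13,2013,europe,free_translation,other,geriatric_residence,23.0,4.0,24.0,7.3,45.1,7.2
S25,0.761266,24,13,2008,asia,validated,other,geriatric_residence,22.0,2.0,48.8,8.2,,
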
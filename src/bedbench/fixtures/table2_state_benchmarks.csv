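state,actual,unadjusted,adjusted,ci_low,ci_high,printed_label
Colorado,114.3,32.74,31.44,25.67,37.2,Actual > Needed
Louisiana,126.68,34.05,40.63,29.99,51.28,Actual > Needed
Arizona,110.47,38.29,35.99,30.72,41.27,Actual > Needed
Missouri,82.49,30.58,29.21,25.35,33.08,Actual > Needed
Montana,53.89,26.46,26.06,20.39,31.73,Actual > Needed
Florida,69.8,36.68,38.91,32.35,45.48,Actual > Needed
Connecticut,59.1,72.37,37.46,19.69,55.23,Actual > Needed
Alaska,46.52,30.55,30.32,24.9,35.73,Actual > Needed
Kansas,38.51,26.45,25.33,21.65,29,Actual > Needed
Arkansas,48.25,31.78,31.76,23.75,39.78,Actual > Needed
Wyoming,36.63,25.34,24.66,20.68,28.64,Actual > Needed
North Dakota,38.45,29.62,28.39,22.73,34.05,Actual > Needed
Delaware,38.72,26.27,31.65,27.12,36.17,Actual > Needed
Utah,28.45,23.58,23.6,18.35,28.86,Actual = Needed (w/95%)
New Jersey,42.23,35.96,35.1,27.23,42.98,Actual = Needed (w/95%)
Nebraska,30.97,26.98,26.23,21.84,30.62,Actual > Needed
West Virginia,45.87,42.9,40.82,22.77,58.86,Actual = Needed (w/95%)
Indiana,30.9,29.06,27.68,23.81,31.54,Actual = Needed (w/95%)
Pennsylvania,35.76,33.01,32.65,27.05,38.24,Actual = Needed (w/95%)
Virginia,32.58,29.83,30,26.08,33.91,Actual = Needed (w/95%)
Alabama,33.65,33.66,31.84,25.97,37.72,Actual = Needed (w/95%)
Mississippi,38.71,39.07,38.15,25.8,50.49,Actual = Needed (w/95%)
Ohio,28.83,30.55,30.03,25.11,34.95,Actual = Needed (w/95%)
Tennessee,27.72,30.72,29.17,24.99,33.34,Actual = Needed (w/95%)
Iowa,24.18,27.38,26.15,22.1,30.2,Actual = Needed (w/95%)
Illinois,31.27,32.54,34.27,27.18,41.36,Actual = Needed (w/95%)
Michigan,29.83,35.18,33.4,28.51,38.28,Actual = Needed (w/95%)
Vermont,30.93,37.76,35.17,24.16,46.19,Actual = Needed (w/95%)
New York,42.7,52.22,49.45,36.29,62.6,Actual = Needed (w/95%)
Wisconsin,24.35,29.53,28.62,24.64,32.6,Actual < Needed
North Carolina,25.05,27.6,29.57,25.83,33.31,Actual < Needed
Maine,31.39,37.3,37.32,25.1,49.54,Actual = Needed (w/95%)
Rhode Island,41.35,51.97,49.42,34.85,63.99,Actual = Needed (w/95%)
South Carolina,26.24,30.75,31.48,26.74,36.22,Actual < Needed
Kentucky,29.61,38.22,35.9,24.42,47.37,Actual = Needed (w/95%)
Massachusetts,32.62,40.5,39.55,31.44,47.66,Actual = Needed (w/95%)
Texas,24.66,23.45,30.28,25.12,35.43,Actual < Needed
Washington,24.73,32.58,30.89,25.12,36.66,Actual < Needed
Idaho,19.7,23.96,24.86,19.48,30.24,Actual = Needed (w/95%)
Minnesota,23.23,30.96,29.43,24.32,34.54,Actual < Needed
Oklahoma,21.33,26,27.18,23.12,31.24,Actual < Needed
Maryland,26.6,35.49,34.53,28.19,40.87,Actual < Needed
California,33.3,34.92,43.54,35.03,52.06,Actual < Needed
New Hampshire,20.37,28.18,26.86,22.71,31,Actual < Needed
New Mexico,31.95,40.78,43.29,33.25,53.33,Actual < Needed
South Dakota,19.1,27.29,26.5,22.25,30.75,Actual < Needed
Oregon,25.27,38.32,35.98,27.67,44.29,Actual < Needed
Hawaii,24.3,23.47,37.16,24.63,49.69,Actual < Needed
Georgia,18.89,27.4,31.46,26.58,36.33,Actual < Needed
Nevada,18.15,28.03,35.41,28.76,42.07,Actual < Needed
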